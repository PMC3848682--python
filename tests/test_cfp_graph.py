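"""Exactness of the Bloom + cFP structure against a hash-set oracle."""

import numpy as np
import pytest

from bloomdbg.cfp_graph import (
    ExactGraph,
    build_bloom,
    build_cfp,
    build_graph,
    enumerate_positive_extensions,
)
from bloomdbg.kmer_core import canonical_array, extensions_array
from bloomdbg.kmer_counting import SolidKmerList
from bloomdbg.synthetic_eval import HashSetGraph


def random_solid(n, k, seed):
    rng = np.random.default_rng(seed)
    vals = np.unique(
        canonical_array(rng.integers(0, 4**k, size=2 * n, dtype=np.uint64), k)
    )
    return SolidKmerList(vals[:n], k=k)


def brute_force_cfp(solid, bloom):
    """cFP = {e in E : bloom(e) and e not in S}, all in memory."""
    ext = np.unique(
        canonical_array(extensions_array(solid.values, solid.k).ravel(), solid.k)
    )
    positive = ext[bloom.contains(ext)]
    return positive[~np.isin(positive, solid.values)]


def test_build_bloom_holds_every_node():
    solid = random_solid(5000, 15, seed=1)
    bloom = build_bloom(solid, r=8, seed=3)
    assert bloom.contains(solid.values).all()
    assert abs(bloom.m - 8 * solid.count) <= 1
    assert bloom.h == 6  # round(8 ln 2)


def test_positive_extensions_properties(tmp_path):
    solid = random_solid(3000, 11, seed=2)
    bloom = build_bloom(solid, r=8, seed=3)
    p_path = enumerate_positive_extensions(solid, bloom, work_dir=tmp_path)
    p = np.fromfile(p_path, dtype=np.uint64)
    assert p.size <= 8 * solid.count
    assert (p[1:] > p[:-1]).all()  # sorted, deduplicated
    assert bloom.contains(p).all()  # every member is Bloom-positive


def test_cfp_equals_brute_force(tmp_path):
    for seed in (1, 2, 3):
        solid = random_solid(10_000, 11, seed=seed)
        bloom = build_bloom(solid, r=8, seed=seed + 10)
        p_path = enumerate_positive_extensions(solid, bloom, work_dir=tmp_path)
        cfp = build_cfp(p_path, solid)
        expect = brute_force_cfp(solid, bloom)
        assert np.array_equal(cfp, expect)
        # defining properties
        assert not np.isin(cfp, solid.values).any()
        assert bloom.contains(cfp).all()


def test_cfp_independent_of_memory_budget(tmp_path):
    solid = random_solid(5000, 13, seed=7)
    bloom = build_bloom(solid, r=7, seed=1)
    results = []
    for budget in (1 << 12, 1 << 16, 1 << 26):
        p_path = enumerate_positive_extensions(solid, bloom, work_dir=tmp_path)
        results.append(build_cfp(p_path, solid, memory_budget=budget))
    assert np.array_equal(results[0], results[1])
    assert np.array_equal(results[1], results[2])


def test_cfp_budget_too_small(tmp_path):
    solid = random_solid(100, 11, seed=1)
    bloom = build_bloom(solid, r=8, seed=1)
    p_path = enumerate_positive_extensions(solid, bloom, work_dir=tmp_path)
    with pytest.raises(ValueError, match="memory_budget"):
        build_cfp(p_path, solid, memory_budget=8)


def test_huge_filter_has_no_critical_false_positives():
    solid = random_solid(2000, 21, seed=5)
    graph = build_graph(solid, r=40, seed=1)
    assert graph.cfp.size == 0


def test_membership_exact_over_extension_set(solid_from_sequence, random_genome):
    genome = random_genome(10_000, seed=31)
    solid = solid_from_sequence(genome, 21)
    graph = build_graph(solid, r=8, seed=2)
    oracle = HashSetGraph.from_solid(solid)
    ext = np.unique(canonical_array(extensions_array(solid.values, 21).ravel(), 21))
    assert np.array_equal(graph.contains_batch(ext), oracle.contains_batch(ext))
    # and membership over E is literally "is in S"
    assert np.array_equal(graph.contains_batch(ext), np.isin(ext, solid.values))


def test_neighbors_on_linear_genome(solid_from_sequence, random_genome):
    genome = random_genome(2000, seed=8)
    k = 21
    solid = solid_from_sequence(genome, k)
    graph = build_graph(solid, r=8, seed=4)
    oracle = HashSetGraph.from_solid(solid)
    values = [int(v) for v in solid.values]
    for x in values[:200]:
        assert graph.neighbors(x) == oracle.neighbors(x)
    # interior nodes of a repeat-free linear genome have exactly 2 neighbors
    from bloomdbg.kmer_core import canonical, encode_kmer

    interior = canonical(encode_kmer(genome[500 : 500 + k]), k)
    assert len(graph.neighbors(interior)) == 2


def test_neighbor_relation_symmetric(solid_from_sequence, random_genome):
    genome = random_genome(1000, seed=77)
    solid = solid_from_sequence(genome, 11)
    graph = build_graph(solid, r=8, seed=9)
    nb = {int(x): {y for y, _, _ in graph.neighbors(int(x))} for x in solid.values}
    for x, ys in nb.items():
        for y in ys:
            assert x in nb[y]


def test_isolated_node_has_no_neighbors():
    # one lonely k-mer: its extensions are not in S
    solid = SolidKmerList(np.array([123456], dtype=np.uint64), k=15)
    graph = build_graph(solid, r=30, seed=1)
    assert graph.neighbors(123456) == []


def test_graph_save_load(tmp_path):
    solid = random_solid(2000, 13, seed=3)
    graph = build_graph(solid, r=8, seed=6)
    graph.save(tmp_path / "g")
    back = ExactGraph.load(tmp_path / "g")
    assert back.k == 13
    assert np.array_equal(back.cfp, graph.cfp)
    assert np.array_equal(back.bloom.words, graph.bloom.words)
    assert back.contains_batch(solid.values).all()
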