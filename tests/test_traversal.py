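"""Marking structure, path operations, bounded BFS and contig assembly."""

import numpy as np
import pytest

from bloomdbg.kmer_core import (
    canonical,
    canonical_array,
    encode_kmer,
    kmers_of_sequence,
)
from bloomdbg.kmer_counting import SolidKmerList
from bloomdbg.synthetic_eval import HashSetGraph
from bloomdbg.traversal import (
    AssemblyParams,
    GraphView,
    MarkingStructure,
    _revcomp_str,
    assemble,
    bounded_bfs,
    extend_simple_path,
    is_complex,
    is_short_tip,
    skip_tips,
)

K = 15


def graph_of(*sequences, k=K):
    vals = [kmers_of_sequence(s, k) for s in sequences]
    nodes = np.unique(canonical_array(np.concatenate(vals), k))
    solid = SolidKmerList(nodes, k=k)
    return HashSetGraph.from_solid(solid), solid


def node(seq, k=K):
    return canonical(encode_kmer(seq), k)


def other_base(b):
    """A base different from b (forces a real fork in constructions)."""
    return "A" if b != "A" else "C"


@pytest.fixture
def linear(random_genome):
    genome = random_genome(400, seed=42)
    g, solid = graph_of(genome)
    return genome, g, solid


def test_is_complex_on_linear_genome(linear):
    genome, g, _ = linear
    assert not is_complex(g, node(genome[100 : 100 + K]))  # interior: in=out=1
    assert is_complex(g, node(genome[:K]))  # endpoint: degree 0 on one side
    assert is_complex(g, node(genome[-K:]))


def test_is_complex_at_three_way_branch(random_genome):
    stem = random_genome(60, seed=1)
    x = random_genome(60, seed=2)
    b1 = stem + x
    b2 = stem + other_base(x[0]) + random_genome(59, seed=3)
    g, _ = graph_of(b1, b2)
    assert is_complex(g, node(stem[-K:]))  # out-degree 2
    assert not is_complex(g, node(b1[len(stem) + 5 : len(stem) + 5 + K]))


def test_marking_structure(linear):
    genome, g, _ = linear
    ms = MarkingStructure(g)
    end = node(genome[:K])
    assert not ms.is_marked(end)
    ms.mark(end)
    assert ms.is_marked(end)
    ms.mark(end)  # idempotent
    assert ms.n_complex == 1
    assert ms.size_bits(K) == 2 * K + 8
    with pytest.raises(ValueError, match="not complex"):
        ms.mark(node(genome[100 : 100 + K]))


def test_extend_simple_path_covers_linear_genome(linear):
    genome, g, solid = linear
    start = encode_kmer(genome[:K])
    path = extend_simple_path(g, start)
    assert len(path) == solid.count - 1  # every other node, in order
    seq = genome[:K] + "".join("ACGT"[v & 3] for v in path)
    assert seq == genome


def test_extend_simple_path_stops_at_branch(random_genome):
    stem = random_genome(60, seed=5)
    x = random_genome(50, seed=6)
    g, _ = graph_of(stem + x, stem + other_base(x[0]) + random_genome(49, seed=7))
    path = extend_simple_path(g, encode_kmer(stem[:K]))
    # walks to the fork node and stops (fork has forward degree 2)
    seq = stem[:K] + "".join("ACGT"[v & 3] for v in path)
    assert seq == stem


def test_extend_simple_path_terminates_on_cycle(random_genome):
    gen = random_genome(200, seed=9)
    circ = gen + gen[: K - 1]
    g, solid = graph_of(circ)
    path = extend_simple_path(g, encode_kmer(circ[:K]))
    assert len(path) == solid.count - 1  # wraps once, never revisits


def test_short_tips_are_skipped(random_genome):
    main = random_genome(300, seed=10)
    fork_at = 150
    stem = main[:fork_at]
    # 6 tip nodes, well under 2K+1, forking off on a different base
    tip = stem + other_base(main[fork_at]) + random_genome(5, seed=11)
    g, _ = graph_of(main, tip)
    fork = encode_kmer(stem[-K:])
    view = GraphView(g)
    raw = view.fwd(fork)
    assert len(raw) == 2
    kept = skip_tips(g, fork, view=view)
    assert len(kept) == 1
    assert "ACGT"[kept[0] & 3] == main[fork_at]


def test_tip_of_exactly_2k_plus_1_nodes_is_kept(random_genome):
    main = random_genome(300, seed=12)
    stem = main[:150]
    # branch contributing exactly 2K+1 nodes: needs 2K+1 extra bases
    tip = stem + other_base(main[150]) + random_genome(2 * K, seed=13)
    g, _ = graph_of(main, tip)
    fork = encode_kmer(stem[-K:])
    view = GraphView(g)
    assert len(skip_tips(g, fork, view=view)) == 2
    branch = [x for x in view.fwd(fork) if "ACGT"[x & 3] == tip[150]][0]
    assert not is_short_tip(g, branch, view=view)


def test_bounded_bfs_resolves_bubble(random_genome):
    left = random_genome(60, seed=14)
    mid_a = random_genome(20, seed=15)
    mid_b = other_base(mid_a[0]) + random_genome(19, seed=16)
    right = random_genome(60, seed=17)
    g, _ = graph_of(left + mid_a + right, left + mid_b + right)
    origin = encode_kmer(left[-K:])
    res = bounded_bfs(g, origin)
    assert res is not None
    path, explored = res
    chosen = "".join("ACGT"[v & 3] for v in path)
    assert chosen in (mid_a + right[: len(chosen) - 20], mid_b + right[: len(chosen) - 20])
    assert len(explored) >= len(path)


def test_bounded_bfs_depth_bound(random_genome):
    stem = random_genome(40, seed=18)
    x = random_genome(100, seed=19)
    a = stem + x  # divergent, never rejoin
    b = stem + other_base(x[0]) + random_genome(99, seed=20)
    g, _ = graph_of(a, b)
    assert bounded_bfs(g, encode_kmer(stem[-K:]), max_depth=50) is None


def test_bounded_bfs_breadth_bound(random_genome):
    stem = random_genome(40, seed=21)
    seqs = [stem + b + random_genome(40, seed=22 + i)
            for i, b in enumerate("ACG")]  # three-way fork
    g, _ = graph_of(*seqs)
    assert bounded_bfs(g, encode_kmer(stem[-K:]), max_breadth=2, max_depth=30) is None


# ---------------------------------------------------------------------------
# assembly


def test_roundtrip_single_contig(random_genome):
    genome = random_genome(2000, seed=30)
    g, solid = graph_of(genome, k=21)
    res = assemble(g, solid, AssemblyParams())
    assert len(res.contigs) == 1
    assert res.contigs[0].sequence in (genome, _revcomp_str(genome))
    # exactly the two endpoint nodes are complex and marked
    assert res.stats["n_complex_marked"] == 2


def test_repeat_genome_fragments_into_substrings(random_genome):
    base = random_genome(3000, seed=31)
    unit = base[500:900]
    genome = base[:1500] + unit + base[1500:]  # unit now occurs twice
    g, solid = graph_of(genome, k=21)
    res = assemble(g, solid, AssemblyParams())
    assert len(res.contigs) >= 2
    rc = _revcomp_str(genome)
    assert all(c.sequence in genome or c.sequence in rc for c in res.contigs)


def test_short_contigs_discarded(random_genome):
    genome = random_genome(70, seed=32)  # shorter than the 100 bp cutoff
    g, solid = graph_of(genome, k=21)
    res = assemble(g, solid, AssemblyParams())
    assert res.contigs == []
    assert res.stats["n_discarded_short"] >= 1
    res2 = assemble(g, solid, AssemblyParams(min_contig=50))
    assert [c.sequence for c in res2.contigs] != []


def test_no_node_in_two_contigs(random_genome):
    base = random_genome(4000, seed=33)
    genome = base[:2000] + base[500:900] + base[2000:]
    g, solid = graph_of(genome, k=21)
    res = assemble(g, solid, AssemblyParams())
    seen = []
    for c in res.contigs:
        seen.append(canonical_array(kmers_of_sequence(c.sequence, 21), 21))
    cat = np.concatenate(seen)
    assert len(cat) == len(np.unique(cat))
    # every emitted k-mer is a graph node
    assert np.isin(cat, solid.values).all()


def test_assembly_deterministic(random_genome):
    genome = random_genome(3000, seed=34)
    g, solid = graph_of(genome, k=21)
    a = assemble(g, solid, AssemblyParams())
    b = assemble(g, solid, AssemblyParams())
    assert [c.sequence for c in a.contigs] == [c.sequence for c in b.contigs]
    assert [c.start_node for c in a.contigs] == [c.start_node for c in b.contigs]


def test_marking_scheme_equivalent_to_marking_every_node(random_genome):
    # complex-node port marks must reproduce the assembly of a variant
    # that records every visited node explicitly
    for seed in (35, 36, 37):
        base = random_genome(3000, seed=seed)
        genome = base[:1500] + base[200:600] + base[1500:]
        g, solid = graph_of(genome, k=15)
        ports = assemble(g, solid, AssemblyParams())
        full = assemble(g, solid, AssemblyParams(mark_all_nodes=True))
        assert [c.sequence for c in ports.contigs] == [c.sequence for c in full.contigs]


def test_circular_genome_assembles_once(random_genome):
    gen = random_genome(1500, seed=38)
    circ = gen + gen[:20]
    g, solid = graph_of(circ, k=21)
    res = assemble(g, solid, AssemblyParams())
    assert len(res.contigs) == 1
    c = res.contigs[0].sequence
    assert len(c) == 1500 + 20  # one full turn plus the k-1 wrap
    doubled = gen + gen
    assert c in doubled or _revcomp_str(c) in doubled
    assert res.stats["n_complex_marked"] == 0  # no complex node anywhere
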