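"""Synthetic genomes, simulated reads, and the probabilistic-vs-exact
structure comparison.

The generator emulates the simplest shotgun setting that still
exercises every part of the pipeline: an i.i.d. uniform random genome
(optionally with planted exact repeats), reads of fixed length drawn
uniformly from both strands, and independent per-base substitution
errors.  No indels, no quality values, no coverage biases — enough to
produce solid-k-mer filtering, tips and bubbles, but deliberately not
a sequencer model.

``compare_structures`` is the desk-scale version of the key
experiment: across a grid of Bloom-filter sizes (bits per k-mer), the
exact structure (filter + cFP) must reproduce, at every size, the
assembly obtained from a plain hash-set de Bruijn graph, while the
Bloom-only structure drifts away as the filter shrinks.  Assemblies
are compared by exact full-length substring matching rather than
alignment — a dependency-free proxy that is sufficient when
differences are whole missing or altered contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from .bloom_filter import BloomFilter
from .cfp_graph import ExactGraph, build_bloom, build_graph
from .kmer_counting import SolidKmerList
from .kmer_core import canonical, extensions
from .traversal import AssemblyParams, Contig, assemble

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment."""

    genome_length: int = 100_000
    read_length: int = 100
    coverage: float = 40.0
    substitution_error_rate: float = 0.01
    seed: int = 1
    repeat_spec: Optional[tuple[int, int]] = None  # (unit length, copies)

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.substitution_error_rate < 1.0:
            raise ValueError("error rate must be in [0, 1)")


def generate_genome(cfg: SimulationConfig) -> str:
    """Uniform random ACGT sequence, deterministic in the seed.

    With ``repeat_spec=(L, c)`` an L-base unit sampled from the genome
    is copied over c non-overlapping positions, planting exact repeats
    (the classic obstacle to contig extension)."""
    rng = np.random.default_rng(cfg.seed)
    g = rng.integers(0, 4, size=cfg.genome_length, dtype=np.uint8)
    if cfg.repeat_spec is not None:
        unit_len, copies = cfg.repeat_spec
        if unit_len > cfg.genome_length // max(copies, 1):
            raise ValueError("repeat unit too long for the genome")
        starts = np.arange(copies) * (cfg.genome_length // copies)
        offset = int(rng.integers(0, cfg.genome_length // copies - unit_len + 1))
        unit = g[starts[0] + offset : starts[0] + offset + unit_len].copy()
        for s in starts:
            g[s + offset : s + offset + unit_len] = unit
    return _BASES[g].tobytes().decode("ascii")


def simulate_reads(genome: str, cfg: SimulationConfig) -> list[str]:
    """ceil(coverage * G / L) reads of length L from uniform positions
    on both strands, with i.i.d. substitution errors; deterministic in
    the seed.

    The first two reads are pinned to the genome's two ends (forward
    strand) so that terminal k-mers are observable at d=1; with purely
    uniform starts the expected number of reads touching base 0 is
    coverage/L and the ends would usually be ragged."""
    G, L = len(genome), cfg.read_length
    if L > G:
        raise ValueError("read length exceeds genome length")
    rng = np.random.default_rng(cfg.seed + 0x5EED)
    n_reads = int(np.ceil(cfg.coverage * G / L))
    codes = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    lut[ord("A")], lut[ord("C")], lut[ord("G")], lut[ord("T")] = 0, 1, 2, 3
    codes = lut[codes]
    starts = rng.integers(0, G - L + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    if n_reads >= 2:
        starts[0], strands[0] = 0, 0
        starts[1], strands[1] = G - L, 0
    reads = []
    for s, rev in zip(starts, strands):
        r = codes[s : s + L]
        if rev:
            r = 3 - r[::-1]
        if cfg.substitution_error_rate > 0:
            err = rng.random(L) < cfg.substitution_error_rate
            if err.any():
                r = r.copy()
                shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
                r[err] = (r[err] + shift) % 4
        reads.append(_BASES[r].tobytes().decode("ascii"))
    return reads


# ---------------------------------------------------------------------------
# reference (oracle) graph and the Bloom-only structure


class HashSetGraph:
    """Plain de Bruijn graph over an explicit node set — the exactness
    oracle.  Same membership interface as :class:`ExactGraph`."""

    def __init__(self, nodes: np.ndarray, k: int):
        self.nodes = np.sort(np.asarray(nodes, dtype=np.uint64))
        self.k = int(k)

    @classmethod
    def from_solid(cls, solid: SolidKmerList) -> "HashSetGraph":
        return cls(solid.values, solid.k)

    def contains_batch(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=np.uint64)
        if self.nodes.size == 0:
            return np.zeros(v.size, dtype=bool)
        idx = np.minimum(np.searchsorted(self.nodes, v), self.nodes.size - 1)
        return self.nodes[idx] == v

    def contains(self, x: int) -> bool:
        return bool(self.contains_batch(np.array([x], dtype=np.uint64))[0])

    def neighbors(self, x: int) -> list[tuple[int, str, int]]:
        ext = extensions(x, self.k)
        canon = np.fromiter((canonical(e, self.k) for e in ext),
                            dtype=np.uint64, count=8)
        hit = self.contains_batch(canon)
        out, seen = [], set()
        for i in range(8):
            if hit[i]:
                key = (int(canon[i]), "right" if i < 4 else "left", i % 4)
                if key not in seen:
                    seen.add(key)
                    out.append(key)
        return out


def probabilistic_only_graph(bloom: BloomFilter, k: int) -> ExactGraph:
    """The Bloom filter alone, with an empty cFP set: membership has
    false positives and neighbor sets are supersets of the true ones."""
    return ExactGraph(bloom, np.empty(0, dtype=np.uint64), k=k)


# ---------------------------------------------------------------------------
# assembly comparison


def assembly_difference(contigs_a: Sequence[Contig],
                        contigs_ref: Sequence[Contig]) -> int:
    """Total bases by which assembly A differs from the reference:
    bases in A-contigs that are not full-length substrings of any
    reference contig (either strand), plus reference bases not covered
    by any matching A-contig."""
    from .traversal import _revcomp_str

    refs = [c.sequence for c in contigs_ref]
    covered = [np.zeros(len(r), dtype=bool) for r in refs]
    unmatched = 0
    for c in contigs_a:
        seq = c.sequence
        hit = False
        for variant in (seq, _revcomp_str(seq)):
            for i, r in enumerate(refs):
                pos = r.find(variant)
                if pos >= 0:
                    covered[i][pos : pos + len(variant)] = True
                    hit = True
                    break
            if hit:
                break
        if not hit:
            unmatched += len(seq)
    uncovered = sum(int((~cov).sum()) for cov in covered)
    return unmatched + uncovered


@dataclass
class StructurePoint:
    """Measured sizes and assembly fidelity at one Bloom ratio r."""

    r: float
    bloom_bits: int
    cfp_count: int
    cfp_bits: int
    marking_entries: int
    marking_bits: int
    exact_difference: int
    probabilistic_difference: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ComparisonReport:
    k: int
    n_solid: int
    points: list[StructurePoint]
    reference_contigs: int
    reference_bases: int

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "n_solid": self.n_solid,
            "reference_contigs": self.reference_contigs,
            "reference_bases": self.reference_bases,
            "points": [p.as_dict() for p in self.points],
        }


DEFAULT_R_GRID = (5.0, 7.0, 9.0, 11.0, 13.0, 15.0, 17.0, 19.0)


def plot_report(report: "ComparisonReport", path) -> None:
    """Two-panel summary of a comparison report: per-component structure
    sizes (bits per k-mer) and assembly difference from the reference,
    both against the Bloom ratio r.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = report.n_solid
    rs = [p.r for p in report.points]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.plot(rs, [p.bloom_bits / n for p in report.points], "o-", label="Bloom filter")
    ax1.plot(rs, [p.cfp_bits / n for p in report.points], "s-", label="cFP set")
    ax1.plot(rs, [p.marking_bits / n for p in report.points], "^-", label="marking")
    ax1.set_xlabel("Bloom filter bits per k-mer (r)")
    ax1.set_ylabel("structure size (bits per k-mer)")
    ax1.legend(frameon=False, fontsize=8)
    ax2.plot(rs, [p.exact_difference for p in report.points], "o-",
             label="exact (Bloom + cFP)")
    ax2.plot(rs, [p.probabilistic_difference for p in report.points], "s-",
             label="Bloom only")
    ax2.set_xlabel("Bloom filter bits per k-mer (r)")
    ax2.set_ylabel("assembly difference (bases)")
    ax2.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def compare_structures(
    solid: SolidKmerList,
    r_grid: Sequence[float] = DEFAULT_R_GRID,
    seed: int = 1,
    params: Optional[AssemblyParams] = None,
) -> ComparisonReport:
    """For each Bloom ratio in the grid, build the exact and the
    Bloom-only structures, assemble with the identical traversal, and
    measure structure sizes plus the base-level difference from the
    hash-set reference assembly.  The exact structure's difference is
    zero by construction of cFP."""
    params = params or AssemblyParams()
    oracle = HashSetGraph.from_solid(solid)
    ref = assemble(oracle, solid, params)
    points = []
    for r in r_grid:
        bloom = build_bloom(solid, r=r, seed=seed)
        exact = build_graph(solid, r=r, seed=seed)
        prob = probabilistic_only_graph(bloom, solid.k)
        res_exact = assemble(exact, solid, params)
        res_prob = assemble(prob, solid, params)
        points.append(StructurePoint(
            r=float(r),
            bloom_bits=exact.bloom_bits,
            cfp_count=int(exact.cfp.size),
            cfp_bits=exact.cfp_bits,
            marking_entries=res_exact.stats["n_complex_marked"],
            marking_bits=res_exact.stats["marking_bits"],
            exact_difference=assembly_difference(res_exact.contigs, ref.contigs),
            probabilistic_difference=assembly_difference(res_prob.contigs, ref.contigs),
        ))
    return ComparisonReport(
        k=solid.k,
        n_solid=solid.count,
        points=points,
        reference_contigs=len(ref.contigs),
        reference_bases=sum(c.length for c in ref.contigs),
    )
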