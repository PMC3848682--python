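"""End-to-end pipeline: counting -> Bloom filter -> positive
extensions -> cFP -> assembly, with a JSON-able run report.

Step order and report granularity mirror the construction stages of
the structure itself, so per-step element counts and bits-per-k-mer
figures can be read off directly.  Memory budgets are advisory
contracts on working-set element counts, not enforced process limits.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .cfp_graph import (
    DEFAULT_MEMORY_BUDGET,
    ExactGraph,
    build_bloom,
    build_cfp,
    default_bits_per_kmer,
    enumerate_positive_extensions,
)
from .kmer_counting import CountingConfig, SolidKmerList, count_kmers
from .traversal import AssemblyParams, assemble


@dataclass
class PipelineConfig:
    k: int = 27
    d: int = 3
    r: Optional[float] = None  # default: the memory-optimal ratio for k
    seed: int = 1
    min_contig: int = 100
    max_depth: int = 500
    max_breadth: int = 20
    num_partitions: int = 4
    work_dir: Optional[Path] = None
    memory_budget: int = DEFAULT_MEMORY_BUDGET

    def resolved_r(self) -> float:
        return self.r if self.r is not None else default_bits_per_kmer(self.k)


@dataclass
class PipelineRun:
    contigs: list
    graph: ExactGraph
    solid: SolidKmerList
    report: dict = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig, reads) -> PipelineRun:
    """Execute the full pipeline on an iterable of read strings (or a
    list of FASTA/FASTQ paths via :mod:`bloomdbg.seqio` upstream)."""
    r = cfg.resolved_r()
    report: dict = {
        "config": {
            "k": cfg.k, "d": cfg.d, "r": r, "seed": cfg.seed,
            "min_contig": cfg.min_contig, "max_depth": cfg.max_depth,
            "max_breadth": cfg.max_breadth,
        },
        "steps": {},
    }

    def step(name):
        t0 = time.perf_counter()

        def done(**counts):
            report["steps"][name] = {"seconds": round(time.perf_counter() - t0, 3),
                                     **counts}
        return done

    done = step("kmer_counting")
    solid = count_kmers(reads, CountingConfig(
        k=cfg.k, d=cfg.d, num_partitions=cfg.num_partitions,
        work_dir=cfg.work_dir))
    done(solid_kmers=solid.count)
    if solid.count == 0:
        raise RuntimeError("kmer_counting produced no solid k-mers "
                           f"(k={cfg.k}, d={cfg.d}); nothing to assemble")

    done = step("enumerating_positive_extensions")
    bloom = build_bloom(solid, r=r, seed=cfg.seed)
    p_path = enumerate_positive_extensions(solid, bloom, work_dir=cfg.work_dir)
    p_count = Path(p_path).stat().st_size // 8
    done(bloom_bits=bloom.m, bloom_hashes=bloom.h, positive_extensions=p_count)

    done = step("constructing_cfp")
    try:
        cfp = build_cfp(p_path, solid, memory_budget=cfg.memory_budget)
    finally:
        Path(p_path).unlink(missing_ok=True)
    graph = ExactGraph(bloom, cfp, k=cfg.k)
    done(cfp_kmers=int(cfp.size))

    done = step("assembly")
    result = assemble(graph, solid, AssemblyParams(
        min_contig=cfg.min_contig, max_depth=cfg.max_depth,
        max_breadth=cfg.max_breadth))
    done(contigs=len(result.contigs),
         total_bases=result.stats["total_bases"],
         complex_marked=result.stats["n_complex_marked"])

    n = solid.count
    report["structure_bits_per_kmer"] = {
        "bloom": bloom.m / n,
        "cfp": graph.cfp_bits / n,
        "marking": (result.stats["marking_bits"] or 0) / n,
    }
    return PipelineRun(contigs=result.contigs, graph=graph, solid=solid,
                       report=report)
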