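"""Analytic dimensioning of the Bloom-filter + cFP graph structure.

For n solid k-mers stored in a Bloom filter at false-positive rate F,
the critical-false-positive set has expected size 8nF (each node has
eight possible extensions) and each stored k-mer costs 2k bits, so the
total structure size is

    size(F) = n * (1.44 log2(1/F) + 16 F k)   bits.

This trade-off is minimised at F* = 2.08 / (16 k), giving the closed
form n * (1.44 log2(16k/2.08) + 2.08) bits: the Bloom filter share
depends on k while the cFP share is a constant 2.08 bits per k-mer.

Byte figures use binary gigabytes (1 GB = 2**30 bytes), the convention
under which the human-genome illustrations (6.8 / 3.7 / 13.7 GB at
n = 2.4e9, k = 27) come out of the formulas above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

GB = float(2**30)  # bytes


def optimal_fp_rate(k: int) -> float:
    """False-positive rate minimising the total structure size: 2.08/(16k)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return 2.08 / (16.0 * k)


def structure_size_bits(n: int, k: int, F: float) -> float:
    """Total size in bits of Bloom filter plus cFP set at rate F."""
    if not 0.0 < F < 1.0:
        raise ValueError(f"F must be in (0, 1), got {F}")
    return n * (1.44 * math.log2(1.0 / F) + 16.0 * F * k)


def optimal_bits_per_kmer(k: int) -> float:
    """Closed form of the minimum of :func:`structure_size_bits` per k-mer:
    1.44 log2(16k/2.08) + 2.08."""
    return 1.44 * math.log2(16.0 * k / 2.08) + 2.08


def self_information_bits(n_nodes: int, k: int) -> float:
    """log2 C(4^k, n_nodes): the minimum number of bits to encode which
    k-mers form the node set.

    Computed with log-gamma; the raw binomial coefficient is
    astronomically large for realistic inputs.
    """
    if n_nodes < 1:
        raise ValueError(f"n_nodes must be >= 1, got {n_nodes}")
    total = 4.0**k
    if n_nodes > total:
        raise ValueError(f"n_nodes={n_nodes} exceeds 4^k={total:.3g}")
    ln2 = math.log(2.0)
    return (
        math.lgamma(total + 1.0)
        - math.lgamma(n_nodes + 1.0)
        - math.lgamma(total - n_nodes + 1.0)
    ) / ln2


def no_cfp_bits_per_kmer(n: int) -> float:
    """Bits per element above which the expected cFP count drops below
    one (F * 8n < 1): r = 1.44 log2(8n)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return 1.44 * math.log2(8.0 * n)


@dataclass
class SizingReport:
    """Memory plan for n solid k-mers at the optimal trade-off point."""

    n: int
    k: int
    F_opt: float
    bloom_bits_per_kmer: float
    cfp_bits_per_kmer: float
    total_bits_per_kmer: float
    total_bytes: float
    total_gb: float
    self_information_bits: float
    self_information_bits_per_kmer: float
    self_information_gb: float
    no_cfp_bits_per_kmer: float
    no_cfp_filter_gb: float

    def as_dict(self) -> dict:
        return asdict(self)

    def pretty(self) -> str:
        lines = [
            f"n = {self.n:,} solid {self.k}-mers",
            f"optimal false-positive rate F*      {self.F_opt:.6g}",
            f"Bloom filter                        {self.bloom_bits_per_kmer:.1f} bits/k-mer",
            f"cFP set                             {self.cfp_bits_per_kmer:.2f} bits/k-mer",
            f"total structure                     {self.total_bits_per_kmer:.1f} bits/k-mer"
            f"  ({self.total_gb:.1f} GB)",
            f"self-information lower bound        {self.self_information_bits_per_kmer:.1f}"
            f" bits/k-mer  ({self.self_information_gb:.1f} GB)",
            f"no-cFP filter would need            {self.no_cfp_bits_per_kmer:.1f}"
            f" bits/k-mer  ({self.no_cfp_filter_gb:.1f} GB)",
        ]
        return "\n".join(lines)


def sizing_report(n: int, k: int) -> SizingReport:
    """Full dimensioning report for ``n`` solid ``k``-mers."""
    F = optimal_fp_rate(k)
    bloom_bpk = 1.44 * math.log2(1.0 / F)
    cfp_bpk = 16.0 * F * k  # = 2.08 for every k
    total_bpk = bloom_bpk + cfp_bpk
    total_bytes = n * total_bpk / 8.0
    si_bits = self_information_bits(n, k)
    no_cfp_r = no_cfp_bits_per_kmer(n)
    return SizingReport(
        n=n,
        k=k,
        F_opt=F,
        bloom_bits_per_kmer=bloom_bpk,
        cfp_bits_per_kmer=cfp_bpk,
        total_bits_per_kmer=total_bpk,
        total_bytes=total_bytes,
        total_gb=total_bytes / GB,
        self_information_bits=si_bits,
        self_information_bits_per_kmer=si_bits / n,
        self_information_gb=si_bits / 8.0 / GB,
        no_cfp_bits_per_kmer=no_cfp_r,
        no_cfp_filter_gb=no_cfp_r * n / 8.0 / GB,
    )
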