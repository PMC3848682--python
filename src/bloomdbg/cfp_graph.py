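"""Exact de Bruijn graph representation: Bloom filter + critical false
positives.

The true nodes S (solid canonical k-mers) are inserted in a Bloom
filter.  Queried alone, the filter over-approximates the graph: some
extensions of true nodes answer *yes* without being in S, creating
false branching.  Those elements — Bloom-positive extensions of S that
are not in S — are the *critical false positives*,

    cFP = P \\ S,   P = {e in E : bloom(e) = yes},

where E is the set of canonicalised 8-extensions of the nodes of S.
Storing cFP alongside the filter makes neighbor queries exact for
every node of S: ``contains(x)`` returns true iff the filter answers
yes and x is not in cFP, which within the extension set E is equivalent
to x in S with zero error.  Membership of an arbitrary k-mer outside E
is intentionally unspecified (such k-mers are never queried when every
traversal starts from a node of S).

cFP is built in bounded memory: P is written to disk, then filtered
against successive partitions D_i of S, holding only one partition and
one chunk of P in memory at a time; all disk access is sequential.
The surviving elements are the critical false positives, kept as a
sorted array of 64-bit integers and queried by binary search.
"""

from __future__ import annotations

import json
import math
import os
import struct
import tempfile
from pathlib import Path
from typing import Optional

import numpy as np

from .bloom_filter import BloomFilter
from .kmer_core import (
    canonical,
    canonical_array,
    extensions,
    extensions_array,
)
from .kmer_counting import SolidKmerList
from .sizing import optimal_fp_rate

_CFP_MAGIC = b"CFPK"
_CFP_HEADER = struct.Struct("<4sBBxxQ")

DEFAULT_MEMORY_BUDGET = 64 << 20  # bytes of working set for cFP construction


def default_bits_per_kmer(k: int) -> float:
    """Memory-optimal Bloom filter ratio r = 1.44 log2(16k/2.08)
    (about 11.1 bits per k-mer at k = 27)."""
    return 1.44 * math.log2(1.0 / optimal_fp_rate(k))


def build_bloom(solid: SolidKmerList, r: Optional[float] = None,
                seed: int = 1) -> BloomFilter:
    """Bloom filter of ceil(r * |S|) bits over all solid k-mers."""
    if solid.count == 0:
        raise ValueError("cannot build a Bloom filter over an empty node set")
    if r is None:
        r = default_bits_per_kmer(solid.k)
    bloom = BloomFilter.for_capacity(solid.count, r=r, k=solid.k, seed=seed)
    for chunk in solid.iter_chunks():
        bloom.insert(chunk)
    return bloom


def enumerate_positive_extensions(
    solid: SolidKmerList,
    bloom: BloomFilter,
    work_dir=None,
    chunk: int = 1 << 19,
) -> Path:
    """Write P — the deduplicated canonical 8-extensions of S for which
    the Bloom filter answers yes — to a raw uint64 file, sorted
    ascending.  |P| <= 8 |S| by construction."""
    k = solid.k
    fd, raw_path = tempfile.mkstemp(prefix="positive_ext_", suffix=".u64",
                                    dir=work_dir)
    os.close(fd)
    raw_path = Path(raw_path)
    with open(raw_path, "wb") as fh:
        for vals in solid.iter_chunks(chunk):
            ext = canonical_array(extensions_array(vals, k).ravel(), k)
            pos = ext[bloom.contains(ext)]
            if pos.size:
                np.unique(pos).tofile(fh)
    # global sort-dedup (chunks above are locally unique only)
    p = np.fromfile(raw_path, dtype=np.uint64)
    np.unique(p).tofile(str(raw_path))
    return raw_path


def build_cfp(
    p_path,
    solid: SolidKmerList,
    memory_budget: int = DEFAULT_MEMORY_BUDGET,
) -> np.ndarray:
    """Compute cFP = P \\ S with a bounded working set.

    S is streamed in ``ceil(8 |S| / budget)`` contiguous partitions
    (S is sorted, so slices are valid partitions); P is filtered chunk
    by chunk against each partition, with survivors rewritten to disk
    between rounds.  The result is independent of the budget.
    """
    p_path = Path(p_path)
    min_budget = 16  # one uint64 of S plus one of P
    if memory_budget < min_budget:
        raise ValueError(
            f"memory_budget={memory_budget} too small; need >= {min_budget} bytes"
        )
    # Half the budget for the S partition, half for the P chunk.
    part_elems = max(1, memory_budget // 16)
    chunk_elems = max(1, memory_budget // 16)
    num_partitions = max(1, math.ceil(solid.count / part_elems))

    work_dir = p_path.parent
    cur_path = p_path
    for i in range(num_partitions):
        d_i = solid.values[i * part_elems : (i + 1) * part_elems]
        if d_i.size == 0:
            continue
        fd, nxt = tempfile.mkstemp(prefix="cfp_round_", suffix=".u64",
                                   dir=work_dir)
        os.close(fd)
        nxt = Path(nxt)
        with open(cur_path, "rb") as src, open(nxt, "wb") as dst:
            while True:
                p_j = np.fromfile(src, dtype=np.uint64, count=chunk_elems)
                if p_j.size == 0:
                    break
                idx = np.minimum(np.searchsorted(d_i, p_j), d_i.size - 1)
                keep = p_j[d_i[idx] != p_j]
                if keep.size:
                    keep.tofile(dst)
        if cur_path != p_path:
            cur_path.unlink()
        cur_path = nxt
    survivors = np.fromfile(cur_path, dtype=np.uint64)
    if cur_path != p_path:
        cur_path.unlink()
    # P was sorted and filtering preserves order.
    assert survivors.size < 2 or (survivors[1:] > survivors[:-1]).all()
    return survivors


class ExactGraph:
    """The combined membership structure: Bloom filter plus cFP set.

    Neighbor queries are exact for every node of S; see module
    docstring for the contract on arbitrary k-mers.
    """

    def __init__(self, bloom: BloomFilter, cfp: np.ndarray, k: int):
        self.bloom = bloom
        self.cfp = np.asarray(cfp, dtype=np.uint64)
        self.k = int(k)

    # -- membership ------------------------------------------------------

    def _in_cfp(self, values: np.ndarray) -> np.ndarray:
        if self.cfp.size == 0:
            return np.zeros(len(values), dtype=bool)
        idx = np.searchsorted(self.cfp, values)
        idx = np.minimum(idx, self.cfp.size - 1)
        return self.cfp[idx] == values

    def contains_batch(self, values: np.ndarray) -> np.ndarray:
        """Membership of canonical k-mers; exact within the extension
        set of S."""
        v = np.asarray(values, dtype=np.uint64)
        hit = self.bloom.contains(v)
        if hit.any():
            hit &= ~self._in_cfp(v)
        return hit

    def contains(self, x: int) -> bool:
        return bool(self.contains_batch(np.array([x], dtype=np.uint64))[0])

    # -- neighbors -------------------------------------------------------

    def neighbors(self, x: int) -> list[tuple[int, str, int]]:
        """Graph neighbors of a canonical node x as
        (canonical neighbor, side, base) with side in {right, left}
        relative to the canonical orientation of x.  Deduplicated,
        fixed order (right A,C,G,T then left A,C,G,T)."""
        k = self.k
        ext = extensions(x, k)
        canon = np.fromiter(
            (canonical(e, k) for e in ext), dtype=np.uint64, count=8
        )
        hit = self.contains_batch(canon)
        out: list[tuple[int, str, int]] = []
        seen = set()
        for i in range(8):
            if not hit[i]:
                continue
            key = (int(canon[i]), "right" if i < 4 else "left", i % 4)
            if key in seen:
                continue
            seen.add(key)
            out.append(key)
        return out

    # -- memory accounting ----------------------------------------------

    @property
    def cfp_bits(self) -> int:
        """cFP storage cost at 64 bits per entry (sorted integer list)."""
        return 64 * int(self.cfp.size)

    @property
    def bloom_bits(self) -> int:
        return self.bloom.m

    # -- serialization ---------------------------------------------------

    def save(self, prefix) -> None:
        """Write <prefix>.bloom, <prefix>.cfp and <prefix>.json."""
        prefix = Path(prefix)
        self.bloom.save(prefix.with_suffix(".bloom"))
        with open(prefix.with_suffix(".cfp"), "wb") as fh:
            fh.write(_CFP_HEADER.pack(_CFP_MAGIC, 1, self.k, self.cfp.size))
            self.cfp.tofile(fh)
        meta = {
            "k": self.k,
            "m": self.bloom.m,
            "h": self.bloom.h,
            "seed": self.bloom.seed,
            "n_inserted": self.bloom.n_inserted,
            "cfp_count": int(self.cfp.size),
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, prefix) -> "ExactGraph":
        prefix = Path(prefix)
        bloom = BloomFilter.load(prefix.with_suffix(".bloom"))
        with open(prefix.with_suffix(".cfp"), "rb") as fh:
            magic, version, k, count = _CFP_HEADER.unpack(fh.read(_CFP_HEADER.size))
            if magic != _CFP_MAGIC or version != 1:
                raise ValueError(f"{prefix}: not a cFP file")
            cfp = np.fromfile(fh, dtype=np.uint64)
        if cfp.size != count:
            raise ValueError(f"{prefix}: truncated cFP array")
        return cls(bloom, cfp, k=k)


def build_graph(
    solid: SolidKmerList,
    r: Optional[float] = None,
    seed: int = 1,
    work_dir=None,
    memory_budget: int = DEFAULT_MEMORY_BUDGET,
) -> ExactGraph:
    """Bloom filter + positive-extension enumeration + cFP filtering,
    in that order; the one-call construction of the exact graph."""
    bloom = build_bloom(solid, r=r, seed=seed)
    p_path = enumerate_positive_extensions(solid, bloom, work_dir=work_dir)
    try:
        cfp = build_cfp(p_path, solid, memory_budget=memory_budget)
    finally:
        p_path.unlink(missing_ok=True)
    return ExactGraph(bloom, cfp, k=solid.k)
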