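"""Disk-partitioned counting of canonical k-mers.

The multiset of canonical k-mers of the reads is split into partitions
by a hash of the packed k-mer, and each partition is appended to its
own temporary file as raw uint64 records.  Partitions are then counted
one at a time in memory, so the peak in-memory state is bounded by the
largest single partition rather than by the full k-mer multiset.
K-mers seen at least ``d`` times are *solid* and become the true nodes
of the graph; ``d = 3`` by default discards most k-mers created by
sequencing errors, while ``d = 1`` keeps everything (useful for
error-free simulations).

Counts saturate at 255 (8-bit counters); only the comparison against
``d`` matters downstream, so saturation is harmless for d <= 255.
"""

from __future__ import annotations

import shutil
import struct
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np

from .kmer_core import canonical_array, kmers_of_sequence

_SOLID_MAGIC = b"SOLK"
_SOLID_HEADER = struct.Struct("<4sBBxxQ")  # magic, version, k, pad, count

_PARTITION_SEED = np.uint64(0xC0FFEE123456789)
_COUNT_CAP = 255


@dataclass
class CountingConfig:
    k: int
    d: int = 3
    num_partitions: int = 4
    work_dir: Optional[Path] = None
    chunk_kmers: int = 1 << 21  # flush buffer threshold

    def __post_init__(self):
        if self.d < 1:
            raise ValueError(f"d must be >= 1, got {self.d}")
        if self.num_partitions < 1:
            raise ValueError("num_partitions must be >= 1")


class SolidKmerList:
    """Sorted, unique canonical k-mers, optionally backed by a file.

    On disk: a small header (magic, version, k, count) followed by the
    packed k-mers as little-endian uint64, ascending.  Ascending order
    is what gives the traversal and the cFP construction a
    deterministic node enumeration.
    """

    def __init__(self, values: np.ndarray, k: int, path: Optional[Path] = None):
        values = np.asarray(values, dtype=np.uint64)
        if values.size > 1 and not (values[1:] > values[:-1]).all():
            raise ValueError("solid k-mer values must be strictly increasing")
        self.values = values
        self.k = int(k)
        self.path = Path(path) if path is not None else None

    @property
    def count(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.count

    def enumerate_nodes(self) -> Iterator[int]:
        """Yield every node ascending, exactly once."""
        for v in self.values:
            yield int(v)

    def __iter__(self) -> Iterator[int]:
        return self.enumerate_nodes()

    def iter_chunks(self, chunk: int = 1 << 20) -> Iterator[np.ndarray]:
        for i in range(0, self.count, chunk):
            yield self.values[i : i + chunk]

    def save(self, path) -> "SolidKmerList":
        path = Path(path)
        with open(path, "wb") as fh:
            fh.write(_SOLID_HEADER.pack(_SOLID_MAGIC, 1, self.k, self.count))
            self.values.tofile(fh)
        self.path = path
        return self

    @classmethod
    def load(cls, path) -> "SolidKmerList":
        path = Path(path)
        with open(path, "rb") as fh:
            magic, version, k, count = _SOLID_HEADER.unpack(fh.read(_SOLID_HEADER.size))
            if magic != _SOLID_MAGIC or version != 1:
                raise ValueError(f"{path}: not a solid k-mer file")
            values = np.fromfile(fh, dtype=np.uint64)
        if values.size != count:
            raise ValueError(f"{path}: expected {count} records, found {values.size}")
        return cls(values, k=k, path=path)


def partition_of(values: np.ndarray, num_partitions: int) -> np.ndarray:
    """Partition index of each canonical k-mer (hash modulo the count)."""
    from .bloom_filter import _mix64

    v = np.asarray(values, dtype=np.uint64)
    return (_mix64(v ^ _PARTITION_SEED) % np.uint64(num_partitions)).astype(np.int64)


def count_kmers(reads: Iterable[str], cfg: CountingConfig) -> SolidKmerList:
    """Count canonical k-mers of ``reads`` and keep those with total
    multiplicity >= d, as a sorted unique list.

    ``reads`` is any iterable of nucleotide strings (windows with
    non-ACGT characters are skipped).  A k-mer and its reverse
    complement contribute to the same counter, and the result is
    independent of read order and of the number of partitions.
    """
    k, d, P = cfg.k, cfg.d, cfg.num_partitions
    tmp_root = Path(tempfile.mkdtemp(prefix="kmercount_", dir=cfg.work_dir))
    try:
        part_paths = [tmp_root / f"part_{i:04d}.u64" for i in range(P)]
        handles = [open(p, "wb") for p in part_paths]
        try:
            buf: list[np.ndarray] = []
            buffered = 0

            def flush():
                nonlocal buf, buffered
                if not buf:
                    return
                vals = np.concatenate(buf)
                parts = partition_of(vals, P)
                order = np.argsort(parts, kind="stable")
                vals, parts = vals[order], parts[order]
                bounds = np.searchsorted(parts, np.arange(P + 1))
                for i in range(P):
                    seg = vals[bounds[i] : bounds[i + 1]]
                    if seg.size:
                        seg.tofile(handles[i])
                buf, buffered = [], 0

            for seq in reads:
                kmers = kmers_of_sequence(seq, k)
                if kmers.size == 0:
                    continue
                buf.append(canonical_array(kmers, k))
                buffered += kmers.size
                if buffered >= cfg.chunk_kmers:
                    flush()
            flush()
        finally:
            for fh in handles:
                fh.close()

        solid_parts = []
        for p in part_paths:
            vals = np.fromfile(p, dtype=np.uint64)
            if vals.size == 0:
                continue
            uniq, counts = np.unique(vals, return_counts=True)
            counts = np.minimum(counts, _COUNT_CAP)
            solid_parts.append(uniq[counts >= d])
        if solid_parts:
            solid = np.sort(np.concatenate(solid_parts))
        else:
            solid = np.empty(0, dtype=np.uint64)
        return SolidKmerList(solid, k=k)
    finally:
        shutil.rmtree(tmp_root, ignore_errors=True)
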