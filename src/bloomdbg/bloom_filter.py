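"""An m-bit, h-hash Bloom filter over canonical k-mers, plus its
false-positive theory.

The filter answers membership with one-sided error: an inserted element
always queries true (no false negatives), while a non-inserted element
queries true with probability

    F = (1 - exp(-h/r))**h,        r = m / n  bits per element,

for n inserted elements and hash functions yielding equally likely
positions.  Minimising F over h gives h ~ 0.7 r and F ~ 0.6185**r;
solving for m at that optimum gives m ~ 1.44 n log2(1/F).

The hash family is h indexed hashes derived from two base hashes of the
packed k-mer by standard double hashing, g_i = h1 + i*h2 mod m.  The
base hashes are splitmix64-style finalisers keyed by a single filter
seed, so the bit-array state is a deterministic function of (seed,
inserted multiset) and independent of insertion order.

The filter is meant to store *canonical* k-mers only; callers must
canonicalise before insert/query (documented contract, not checked).
"""

from __future__ import annotations

import math
import struct
from pathlib import Path

import numpy as np

_U64 = np.uint64
_MAGIC = b"BLMF"

_C1 = 0x9E3779B97F4A7C15
_C2 = 0xBF58476D1CE4E5B9
_C3 = 0x94D049BB133111EB
_MASK64 = 0xFFFFFFFFFFFFFFFF


def _mix64(z: np.ndarray) -> np.ndarray:
    """splitmix64 finaliser, vectorised on uint64 (wrapping arithmetic)."""
    z = (z + _U64(_C1)) & _U64(_MASK64)
    z ^= z >> _U64(30)
    z = (z * _U64(_C2)) & _U64(_MASK64)
    z ^= z >> _U64(27)
    z = (z * _U64(_C3)) & _U64(_MASK64)
    z ^= z >> _U64(31)
    return z


def _mix64_scalar(z: int) -> int:
    z = (z + _C1) & _MASK64
    z ^= z >> 30
    z = (z * _C2) & _MASK64
    z ^= z >> 27
    z = (z * _C3) & _MASK64
    z ^= z >> 31
    return z


def expected_fp_rate(h: float, r: float) -> float:
    """Analytic false-positive rate (1 - e^(-h/r))^h.

    ``h`` may be fractional (the real-valued optimum is h = r ln 2);
    integer h is what a concrete filter uses.
    """
    if r <= 0:
        raise ValueError(f"r must be positive, got {r}")
    if h <= 0:
        raise ValueError(f"h must be positive, got {h}")
    return (1.0 - math.exp(-h / r)) ** h


def optimal_hash_count(r: float) -> int:
    """Integer hash count minimising the false-positive rate: round(r ln 2), >= 1."""
    if r <= 0:
        raise ValueError(f"r must be positive, got {r}")
    return max(1, round(r * math.log(2)))


def bits_for_rate(F: float, n: int) -> int:
    """Bits needed for false-positive rate F at the optimal hash count:
    ceil(1.44 n log2(1/F))."""
    if not 0.0 < F < 1.0:
        raise ValueError(f"F must be in (0, 1), got {F}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return math.ceil(1.44 * n * math.log2(1.0 / F))


class BloomFilter:
    """Bit array of ``m`` bits with ``h`` double-hashed positions per element."""

    def __init__(self, m: int, h: int, k: int, seed: int = 1):
        if m < 1 or h < 1:
            raise ValueError("m and h must be >= 1")
        self.m = int(m)
        self.h = int(h)
        self.k = int(k)
        self.seed = int(seed) & _MASK64
        self.words = np.zeros((self.m + 63) // 64, dtype=np.uint64)
        self.n_inserted = 0
        self._s1 = _U64(_mix64_scalar(self.seed))
        self._s2 = _U64(_mix64_scalar(self.seed ^ _C1))

    @classmethod
    def for_capacity(cls, n: int, r: float, k: int, seed: int = 1) -> "BloomFilter":
        """Filter sized to ``r`` bits per element for ``n`` elements, with
        the optimal hash count for that ratio."""
        if n < 1:
            raise ValueError("n must be >= 1")
        m = max(1, math.ceil(r * n))
        return cls(m=m, h=optimal_hash_count(r), k=k, seed=seed)

    # -- hashing ---------------------------------------------------------

    def _positions(self, values: np.ndarray) -> np.ndarray:
        """(len(values), h) array of bit positions."""
        v = values.astype(np.uint64, copy=False)
        h1 = _mix64(v ^ self._s1)
        h2 = _mix64(v ^ self._s2) | _U64(1)  # odd stride
        i = np.arange(self.h, dtype=np.uint64)
        return (h1[:, None] + i[None, :] * h2[:, None]) % _U64(self.m)

    # -- operations ------------------------------------------------------

    def insert(self, values) -> None:
        """Insert packed canonical k-mers (scalar int or uint64 array)."""
        v = np.atleast_1d(np.asarray(values, dtype=np.uint64))
        if v.size == 0:
            return
        pos = self._positions(v).ravel()
        np.bitwise_or.at(self.words, pos >> _U64(6), _U64(1) << (pos & _U64(63)))
        self.n_inserted += int(v.size)

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Vectorised membership query; boolean array."""
        v = np.asarray(values, dtype=np.uint64)
        if v.size == 0:
            return np.zeros(0, dtype=bool)
        pos = self._positions(v)
        bits = (self.words[(pos >> _U64(6))] >> (pos & _U64(63))) & _U64(1)
        return bits.all(axis=1)

    def contains_one(self, value: int) -> bool:
        return bool(self.contains(np.array([value], dtype=np.uint64))[0])

    def popcount(self) -> int:
        """Number of set bits in the array."""
        return int(np.bitwise_count(self.words).sum())

    @property
    def bits_per_element(self) -> float:
        return self.m / self.n_inserted if self.n_inserted else float("inf")

    # -- serialization ---------------------------------------------------

    _HEADER = struct.Struct("<4sBBHQQQ")  # magic, version, k, h, m, seed, n_inserted

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "wb") as fh:
            fh.write(self._HEADER.pack(_MAGIC, 1, self.k, self.h, self.m,
                                       self.seed, self.n_inserted))
            self.words.tofile(fh)

    @classmethod
    def load(cls, path) -> "BloomFilter":
        path = Path(path)
        with open(path, "rb") as fh:
            raw = fh.read(cls._HEADER.size)
            magic, version, k, h, m, seed, n_ins = cls._HEADER.unpack(raw)
            if magic != _MAGIC or version != 1:
                raise ValueError(f"{path}: not a Bloom filter file")
            bf = cls(m=m, h=h, k=k, seed=seed)
            words = np.fromfile(fh, dtype=np.uint64)
        if words.size != bf.words.size:
            raise ValueError(f"{path}: truncated bit array")
        bf.words = words
        bf.n_inserted = n_ins
        return bf
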