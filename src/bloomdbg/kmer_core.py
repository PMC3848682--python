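"""2-bit packed k-mer primitives.

A k-mer is stored as an unsigned integer, two bits per base (A=0, C=1,
G=2, T=3), with the leftmost base in the most significant bits.  With
this encoding integer order equals lexicographic order on the base
string, so the canonical form of a k-mer is simply the smaller of its
packed value and the packed value of its reverse complement.

``k`` is capped at 31 so every k-mer (and its hash) fits one 64-bit
word.  Scalar functions operate on Python ints; the ``*_array``
variants operate on numpy ``uint64`` arrays and are the hot path for
counting and graph construction.
"""

from __future__ import annotations

import numpy as np

MAX_K = 31
BASES = "ACGT"

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# byte -> 2-bit code, 255 for anything that is not an upper/lowercase ACGT
_BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _b, _c in _CODE.items():
    _BASE_CODES[ord(_b)] = _c
    _BASE_CODES[ord(_b.lower())] = _c

_M2 = 0x3333333333333333
_M4 = 0x0F0F0F0F0F0F0F0F
_M8 = 0x00FF00FF00FF00FF
_M16 = 0x0000FFFF0000FFFF
_MASK64 = 0xFFFFFFFFFFFFFFFF


class KmerError(ValueError):
    """Invalid k-mer input (bad base or k out of range)."""


def kmer_mask(k: int) -> int:
    return (1 << (2 * k)) - 1


def _check_k(k: int) -> None:
    if not 1 <= k <= MAX_K:
        raise KmerError(f"k must be in [1, {MAX_K}], got {k}")


def encode_kmer(sequence: str) -> int:
    """Pack an ACGT string into its 2-bit integer representation.

    Lowercase input is accepted.  Any other character is rejected with
    the position of the offending base.
    """
    k = len(sequence)
    _check_k(k)
    value = 0
    for i, base in enumerate(sequence):
        code = _CODE.get(base.upper())
        if code is None:
            raise KmerError(f"non-ACGT character {base!r} at index {i}")
        value = (value << 2) | code
    return value


def decode_kmer(value: int, k: int) -> str:
    _check_k(k)
    if not 0 <= value < (1 << (2 * k)):
        raise KmerError(f"value {value} out of range for k={k}")
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(BASES[(value >> shift) & 3])
    return "".join(out)


def reverse_complement(value: int, k: int) -> int:
    """Watson-Crick reverse complement of a packed k-mer (an involution).

    In the 2-bit code the complement of a base is its bitwise NOT, so
    the whole operation is a masked complement followed by a 2-bit-group
    reversal of the 64-bit word.
    """
    v = ~value & _MASK64
    v = ((v & _M2) << 2) | ((v >> 2) & _M2)
    v = ((v & _M4) << 4) | ((v >> 4) & _M4)
    v = ((v & _M8) << 8) | ((v >> 8) & _M8)
    v = ((v & _M16) << 16) | ((v >> 16) & _M16)
    v = ((v << 32) | (v >> 32)) & _MASK64
    return v >> (64 - 2 * k)


def reverse_complement_array(values: np.ndarray, k: int) -> np.ndarray:
    """Vectorised :func:`reverse_complement` on a uint64 array."""
    v = np.bitwise_not(values.astype(np.uint64))
    m2, m4, m8, m16 = (np.uint64(m) for m in (_M2, _M4, _M8, _M16))
    two, four, eight, sixteen, thirtytwo = (np.uint64(s) for s in (2, 4, 8, 16, 32))
    v = ((v & m2) << two) | ((v >> two) & m2)
    v = ((v & m4) << four) | ((v >> four) & m4)
    v = ((v & m8) << eight) | ((v >> eight) & m8)
    v = ((v & m16) << sixteen) | ((v >> sixteen) & m16)
    v = (v << thirtytwo) | (v >> thirtytwo)
    return v >> np.uint64(64 - 2 * k)


def canonical(value: int, k: int) -> int:
    """The smaller of a k-mer and its reverse complement.

    Both strands of a DNA molecule are identified with this single
    representative; the function is idempotent.
    """
    rc = reverse_complement(value, k)
    return value if value <= rc else rc


def canonical_array(values: np.ndarray, k: int) -> np.ndarray:
    return np.minimum(values.astype(np.uint64), reverse_complement_array(values, k))


def extensions(value: int, k: int) -> list[int]:
    """The 8 possible neighbors of a k-mer in the de Bruijn graph.

    Fixed order: the four right extensions (k-1 suffix plus A,C,G,T),
    then the four left extensions (A,C,G,T plus k-1 prefix).  Duplicates
    are possible and preserved.
    """
    mask = kmer_mask(k)
    suffix = (value << 2) & mask
    prefix = value >> 2
    hi = 2 * (k - 1)
    return [suffix | b for b in range(4)] + [(b << hi) | prefix for b in range(4)]


def right_extensions(value: int, k: int) -> list[int]:
    mask = kmer_mask(k)
    suffix = (value << 2) & mask
    return [suffix | b for b in range(4)]


def left_extensions(value: int, k: int) -> list[int]:
    prefix = value >> 2
    hi = 2 * (k - 1)
    return [(b << hi) | prefix for b in range(4)]


def extensions_array(values: np.ndarray, k: int) -> np.ndarray:
    """All 8 extensions of each input k-mer, shape ``(8, len(values))``.

    Rows 0-3 are right extensions (base A,C,G,T appended), rows 4-7 left
    extensions (base A,C,G,T prepended), matching :func:`extensions`.
    """
    v = values.astype(np.uint64)
    mask = np.uint64(kmer_mask(k))
    suffix = (v << np.uint64(2)) & mask
    prefix = v >> np.uint64(2)
    hi = np.uint64(2 * (k - 1))
    out = np.empty((8, len(v)), dtype=np.uint64)
    for b in range(4):
        out[b] = suffix | np.uint64(b)
        out[4 + b] = (np.uint64(b) << hi) | prefix
    return out


def kmers_of_sequence(sequence: str, k: int) -> np.ndarray:
    """Packed k-mers of every length-k ACGT window, left to right.

    Windows containing any non-ACGT character (including N) are
    skipped.  Returns a uint64 array; may be empty.
    """
    _check_k(k)
    n = len(sequence) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = _BASE_CODES[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    bad = (codes == 255).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    ok = (cs[k:] - cs[:-k]) == 0
    c = np.where(codes == 255, 0, codes).astype(np.uint64)
    vals = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        vals = (vals << np.uint64(2)) | c[i : i + n]
    return vals[ok]
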