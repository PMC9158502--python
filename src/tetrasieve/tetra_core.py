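"""Tetranucleotide signature primitives.

Counts k-mers (k = 2, 3, 4) on both strands, computes the 136 canonical
tetranucleotide z-values under the maximal-order Markov expectation
(tetranucleotide count predicted from its two trinucleotides and shared
dinucleotide), and scores similarity of two z-vectors with Pearson's
correlation coefficient (PCCD).

Conventions
-----------
* Counting is double-stranded: forward counts plus the counts of each
  k-mer's reverse complement.  This makes z-values exactly strand
  symmetric, so collapsing the 256 tetranucleotides onto the 136
  canonical representatives (lexicographic minimum of each
  reverse-complement pair) loses no information.
* Windows containing a non-ACGT character are skipped.
* Where the Markov variance is undefined or non-positive, z is 0.
* PCCD is the correlation coefficient itself (not ``1 - r``): larger
  values mean more similar signatures, and the sieve keeps pairs with
  PCCD at or above a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, UndefinedCorrelationError

BASES = "ACGT"
N_CANONICAL = 136

# -- encoding tables ---------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_RC_TABLE = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn", "TGCAYRSWMKVHDBNtgcayrswmkvhdbn"
)

_DECODE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC codes handled)."""
    return seq.translate(_RC_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a sequence to int8 codes A,C,G,T -> 0..3; anything else -> -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def codes_to_seq(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for valid (non-negative) codes."""
    return _DECODE_LUT[codes].tobytes().decode("ascii")


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range((k - 1) * 2, -1, -2):
        out.append(BASES[(code >> shift) & 3])
    return "".join(out)


def _rc_perm(k: int) -> np.ndarray:
    """Permutation mapping each k-mer code to its reverse-complement code."""
    perm = np.empty(4**k, dtype=np.int64)
    for code in range(4**k):
        rc = 0
        c = code
        for _ in range(k):
            rc = (rc << 2) | (3 - (c & 3))
            c >>= 2
        perm[code] = rc
    return perm


_RC_PERM = {k: _rc_perm(k) for k in (2, 3, 4)}

# index arrays for the z-value formula, over all 256 tetranucleotides
_LEFT3 = np.arange(256) >> 2          # w1 w2 w3
_RIGHT3 = np.arange(256) & 63         # w2 w3 w4
_MID2 = (np.arange(256) >> 2) & 15    # w2 w3


def canonical_tetranucleotides() -> list[str]:
    """The 136 canonical tetranucleotides, lexicographically sorted.

    Canonical representative = the lexicographically smaller of a
    tetranucleotide and its reverse complement; the 16 palindromes are
    self-canonical.
    """
    out = []
    for code in range(256):
        s = _decode_kmer(code, 4)
        if s <= reverse_complement(s):
            out.append(s)
    return out


_CANON_CODES = np.array(
    [c for c in range(256) if c <= int(_RC_PERM[4][c])], dtype=np.int64
)
assert _CANON_CODES.size == N_CANONICAL


@dataclass(frozen=True)
class ZVector:
    """136 tetranucleotide z-values in canonical order."""

    values: np.ndarray
    source_length_bp: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_CANONICAL,):
            raise InputError(f"ZVector needs {N_CANONICAL} values, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise InputError("ZVector values must be finite")
        object.__setattr__(self, "values", v)


def _count_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Double-stranded k-mer counts over an encoded sequence."""
    n = codes.size
    if n < k:
        return np.zeros(4**k, dtype=np.int64)
    valid = codes >= 0
    safe = np.where(valid, codes, 0).astype(np.int64)
    idx = safe[: n - k + 1].copy()
    ok = valid[: n - k + 1].copy()
    for j in range(1, k):
        idx <<= 2
        idx |= safe[j : n - k + 1 + j]
        ok &= valid[j : n - k + 1 + j]
    fwd = np.bincount(idx[ok], minlength=4**k)
    return fwd + fwd[_RC_PERM[k]]


def count_kmers(seq: str, k: int) -> dict[str, int]:
    """Double-stranded k-mer counts as a {k-mer: count} mapping.

    Counts are summed over the sequence and its reverse complement;
    windows containing non-ACGT characters are skipped.
    """
    if k not in (2, 3, 4):
        raise InputError(f"k must be 2, 3 or 4, got {k}")
    counts = _count_codes(encode(seq), k)
    return {_decode_kmer(c, k): int(counts[c]) for c in range(4**k)}


def _zvalues_from_counts(n4: np.ndarray, n3: np.ndarray, n2: np.ndarray) -> np.ndarray:
    nl = n3[_LEFT3].astype(float)
    nr = n3[_RIGHT3].astype(float)
    nm = n2[_MID2].astype(float)
    safe_nm = np.where(nm > 0, nm, 1.0)
    exp = nl * nr / safe_nm
    var = exp * (1.0 - nl / safe_nm) * (1.0 - nr / safe_nm)
    ok = (nm > 0) & (var > 0)
    z = np.zeros(256)
    np.divide(n4 - exp, np.sqrt(var, where=ok, out=np.ones(256)), where=ok, out=z)
    return z


def zvalues_from_codes(codes: np.ndarray, start: int = 0, end: int | None = None) -> ZVector:
    """Z-values for a slice of an already-encoded sequence (fast path)."""
    sub = codes[start:end]
    if sub.size < 4:
        raise InputError("sequence shorter than 4 bp has no tetranucleotides")
    n4 = _count_codes(sub, 4)
    n3 = _count_codes(sub, 3)
    n2 = _count_codes(sub, 2)
    z = _zvalues_from_counts(n4, n3, n2)
    return ZVector(values=z[_CANON_CODES], source_length_bp=int(sub.size))


def zvalues(seq: str) -> ZVector:
    """136 canonical tetranucleotide z-values of a sequence.

    For canonical tetranucleotide w = w1w2w3w4 with double-stranded
    counts n(.), the expectation and variance under the maximal-order
    Markov model are::

        E   = n(w1w2w3) * n(w2w3w4) / n(w2w3)
        var = E * (1 - n(w1w2w3)/n(w2w3)) * (1 - n(w2w3w4)/n(w2w3))
        z   = (n(w) - E) / sqrt(var)

    with z = 0 wherever n(w2w3) = 0 or var <= 0.
    """
    return zvalues_from_codes(encode(seq))


def pccd(a: ZVector | np.ndarray, b: ZVector | np.ndarray) -> float:
    """Pearson correlation of two 136-dim z-vectors (higher = more similar)."""
    x = np.asarray(a.values if isinstance(a, ZVector) else a, dtype=float)
    y = np.asarray(b.values if isinstance(b, ZVector) else b, dtype=float)
    if x.shape != y.shape:
        raise InputError("vectors must have identical shape")
    xm = x - x.mean()
    ym = y - y.mean()
    nx = float(np.sqrt(np.dot(xm, xm)))
    ny = float(np.sqrt(np.dot(ym, ym)))
    if nx == 0.0 or ny == 0.0:
        raise UndefinedCorrelationError("zero-variance vector in correlation")
    r = float(np.dot(xm, ym) / (nx * ny))
    return max(-1.0, min(1.0, r))
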