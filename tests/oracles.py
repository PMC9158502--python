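"""Independent, deliberately naive re-implementations used as test oracles.

Everything here is written character-by-character / formula-by-formula,
sharing no code with the package internals.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(seq.upper()))


def naive_counts(seq: str, k: int) -> dict[str, int]:
    """Sliding-window double-stranded k-mer counts, dict-based."""
    counts: dict[str, int] = {}
    for strand in (seq.upper(), revcomp(seq)):
        for i in range(len(strand) - k + 1):
            w = strand[i : i + k]
            if any(c not in "ACGT" for c in w):
                continue
            counts[w] = counts.get(w, 0) + 1
    return counts


def naive_canonical() -> list[str]:
    """Brute-force canonical tetranucleotide enumeration over all 256."""
    seen = set()
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                for d in "ACGT":
                    w = a + b + c + d
                    seen.add(min(w, revcomp(w)))
    return sorted(seen)


def naive_zvalues(seq: str) -> dict[str, float]:
    """Literal z-value formula per canonical tetranucleotide."""
    n4 = naive_counts(seq, 4)
    n3 = naive_counts(seq, 3)
    n2 = naive_counts(seq, 2)
    out = {}
    for w in naive_canonical():
        left, right, mid = w[:3], w[1:], w[1:3]
        nm = n2.get(mid, 0)
        if nm == 0:
            out[w] = 0.0
            continue
        exp = n3.get(left, 0) * n3.get(right, 0) / nm
        var = exp * (1 - n3.get(left, 0) / nm) * (1 - n3.get(right, 0) / nm)
        if var <= 0:
            out[w] = 0.0
        else:
            out[w] = (n4.get(w, 0) - exp) / math.sqrt(var)
    return out


def naive_pearson(xs: list[float], ys: list[float]) -> float:
    """Textbook covariance / stddev formula."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    return cov / math.sqrt(vx * vy)


def naive_central_average(values: list[float]) -> float:
    """Sort-and-average of the central 3 (odd) or 4 (even) values."""
    s = sorted(values)
    n = len(s)
    if n == 1:
        return s[0]
    if n == 2:
        return (s[0] + s[1]) / 2
    if n % 2 == 1:
        central = s[n // 2 - 1 : n // 2 + 2]
    else:
        central = s[n // 2 - 2 : n // 2 + 2]
    return sum(central) / len(central)


def naive_gsc(pccds: list[float], legacy: bool = False) -> float:
    n = len(pccds)
    mean = sum(pccds) / n
    if n > 1:
        sd = math.sqrt(sum((p - mean) ** 2 for p in pccds) / (n - 1))
    else:
        sd = 0.0
    return mean - 2 * sd if legacy else mean - sd - 0.01


def naive_ani(blocks: list[tuple[int, int, list[int]]]) -> float:
    """blocks = (stretch_len, n_errors, digits); explicit summation."""
    num = 0
    den = 0
    for stretch, nerr, digits in blocks:
        neg = len([d for d in digits if d < 0])
        num += stretch + neg - nerr
        den += stretch + neg
    return 100.0 * num / den


def naive_union(intervals: list[tuple[int, int]]) -> int:
    """Position-set union length; intervals are 1-based inclusive."""
    positions: set[int] = set()
    for s, e in intervals:
        positions.update(range(min(s, e), max(s, e) + 1))
    return len(positions)


def naive_psg(q_intervals, r_intervals, L1: int, L2: int) -> float:
    return 100.0 * (naive_union(q_intervals) + naive_union(r_intervals)) / (L1 + L2)
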