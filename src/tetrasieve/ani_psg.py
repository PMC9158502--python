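"""ANI and PSG from NUCmer .delta alignments.

Each alignment block in a delta file has a seven-value header (ref
start/end, query start/end, errors, similarity errors, stop codons)
followed by signed indel digits terminated by 0; a negative digit is a
gap (deletion) in the reference.  From those blocks:

    ANI % = sum(stretch + negative_digits - errors)
            / sum(stretch + negative_digits) * 100
    PSG % = (|union of aligned query positions|
             + |union of aligned reference positions|) / (L1 + L2) * 100

where stretch = ref_end - ref_start + 1.  The PSG interval unions
de-duplicate overlapping alignments (repeats, paralogs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import DeltaParseError, InputError


@dataclass(frozen=True)
class DeltaAlignment:
    ref_id: str
    query_id: str
    ref_len: int
    q_len: int
    ref_start: int
    ref_end: int
    q_start: int
    q_end: int
    n_errors: int
    n_sim_errors: int
    n_stop: int
    digits: tuple[int, ...] = field(default_factory=tuple)


def parse_delta(path: str | Path) -> list[DeltaAlignment]:
    """Parse a (nucleotide) NUCmer delta file.

    Coordinates are kept exactly as written (1-based inclusive, query
    coordinates possibly reversed for minus-strand alignments).  A
    PROMER file or a truncated block raises a parse error with the
    offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such delta file: {path}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise DeltaParseError("line 1: delta file truncated")
    if lines[1].strip() != "NUCMER":
        raise DeltaParseError(
            f"line 2: expected NUCMER data type, got {lines[1].strip()!r}"
        )
    alignments: list[DeltaAlignment] = []
    ref_id = query_id = None
    ref_len = q_len = 0
    i = 2
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if line.startswith(">"):
            parts = line[1:].split()
            if len(parts) != 4:
                raise DeltaParseError(f"line {i + 1}: malformed sequence header {line!r}")
            ref_id, query_id = parts[0], parts[1]
            ref_len, q_len = int(parts[2]), int(parts[3])
            i += 1
            continue
        if ref_id is None:
            raise DeltaParseError(f"line {i + 1}: alignment before sequence header")
        fields = line.split()
        if len(fields) != 7:
            raise DeltaParseError(
                f"line {i + 1}: expected 7-value alignment header, got {line!r}"
            )
        try:
            rs, re, qs, qe, nerr, nsim, nstop = (int(x) for x in fields)
        except ValueError as exc:
            raise DeltaParseError(f"line {i + 1}: non-integer header field") from exc
        i += 1
        digits = []
        terminated = False
        while i < n:
            tok = lines[i].strip()
            if not tok:
                i += 1
                continue
            try:
                d = int(tok)
            except ValueError as exc:
                raise DeltaParseError(f"line {i + 1}: expected indel digit") from exc
            i += 1
            if d == 0:
                terminated = True
                break
            digits.append(d)
        if not terminated:
            raise DeltaParseError(f"line {i}: alignment block missing 0 terminator")
        alignments.append(DeltaAlignment(
            ref_id=ref_id, query_id=query_id, ref_len=ref_len, q_len=q_len,
            ref_start=rs, ref_end=re, q_start=qs, q_end=qe,
            n_errors=nerr, n_sim_errors=nsim, n_stop=nstop,
            digits=tuple(digits),
        ))
    return alignments


def write_delta(
    alignments: list[DeltaAlignment],
    path: str | Path,
    ref_file: str = "ref.fa",
    query_file: str = "qry.fa",
) -> None:
    """Serialize alignments as a delta file (fixture/round-trip writer)."""
    groups: dict[tuple[str, str, int, int], list[DeltaAlignment]] = {}
    for a in alignments:
        groups.setdefault((a.ref_id, a.query_id, a.ref_len, a.q_len), []).append(a)
    out = [f"{ref_file} {query_file}", "NUCMER"]
    for (rid, qid, rlen, qlen), alns in groups.items():
        out.append(f">{rid} {qid} {rlen} {qlen}")
        for a in alns:
            out.append(f"{a.ref_start} {a.ref_end} {a.q_start} {a.q_end} "
                       f"{a.n_errors} {a.n_sim_errors} {a.n_stop}")
            out.extend(str(d) for d in a.digits)
            out.append("0")
    Path(path).write_text("\n".join(out) + "\n")


def _stretch(a: DeltaAlignment) -> int:
    return abs(a.ref_end - a.ref_start) + 1


def ani(alignments: list[DeltaAlignment]) -> float:
    """Pooled average nucleotide identity as a percentage.

    All alignments contribute additively to one numerator and one
    denominator (not a mean of per-alignment identities).
    """
    if not alignments:
        raise InputError("ANI needs at least one alignment")
    num = 0
    den = 0
    for a in alignments:
        neg = sum(1 for d in a.digits if d < 0)
        den += _stretch(a) + neg
        num += _stretch(a) + neg - a.n_errors
    if den == 0:
        raise InputError("ANI denominator is zero")
    return 100.0 * num / den


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of a union of 0-based half-open intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def psg(alignments: list[DeltaAlignment], L1: int, L2: int) -> float:
    """Percentage of shared genome; L1 = query length, L2 = reference length.

    Aligned positions are unioned per genome so overlapping alignments
    (repeats, paralogs) count once.  Minus-strand query coordinates
    (start > end) are normalized by swapping.
    """
    if L1 <= 0 or L2 <= 0:
        raise InputError("genome lengths must be positive")
    q_iv: list[tuple[int, int]] = []
    r_iv: list[tuple[int, int]] = []
    for a in alignments:
        qs, qe = sorted((a.q_start, a.q_end))
        rs, re = sorted((a.ref_start, a.ref_end))
        if not (1 <= qs and qe <= L1):
            raise InputError(f"query interval [{qs},{qe}] outside [1,{L1}]")
        if not (1 <= rs and re <= L2):
            raise InputError(f"reference interval [{rs},{re}] outside [1,{L2}]")
        q_iv.append((qs - 1, qe))
        r_iv.append((rs - 1, re))
    return 100.0 * (_union_length(q_iv) + _union_length(r_iv)) / (L1 + L2)
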