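"""Determining stage: all-vs-all signature comparison and rescue.

A pair is sieved when the PCCD between the two ZRFs reaches the pair
cutoff GSC_p, defined as the smaller of the two genome-specific
cutoffs.  Queries that sieve no reference are rescued with the top-N
(default 100) highest-PCCD references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .fragment_signature import Signature

DEFAULT_RESCUE_N = 100


@dataclass(frozen=True)
class SieveRecord:
    query_id: str
    ref_id: str
    pccd: float
    gsc_p: float
    sieved: bool
    rescued: bool
    undefined: bool = False


def _normalized(z: np.ndarray) -> np.ndarray | None:
    """Centered unit-norm copy of a z-vector, or None if zero variance."""
    c = z - z.mean()
    n = float(np.sqrt(np.dot(c, c)))
    if n == 0.0:
        return None
    return c / n


def decide_pair(sig_q: Signature, sig_r: Signature) -> SieveRecord:
    """Evaluate one query/reference pair.

    GSC_p = min(GSC_q, GSC_r); sieved iff PCCD >= GSC_p (inclusive).
    A zero-variance ZRF yields an unsieved record flagged ``undefined``.
    """
    gsc_p = min(sig_q.gsc, sig_r.gsc)
    nq = _normalized(sig_q.zrf.values)
    nr = _normalized(sig_r.zrf.values)
    if nq is None or nr is None:
        return SieveRecord(sig_q.genome_id, sig_r.genome_id, math.nan, gsc_p,
                           sieved=False, rescued=False, undefined=True)
    r = max(-1.0, min(1.0, float(np.dot(nq, nr))))
    return SieveRecord(sig_q.genome_id, sig_r.genome_id, r, gsc_p,
                       sieved=r >= gsc_p, rescued=False)


def rescue(
    query: Signature,
    refs: list[Signature],
    n: int = DEFAULT_RESCUE_N,
) -> list[SieveRecord]:
    """Top-n highest-PCCD references for a query that sieved nothing.

    Ordered descending by PCCD with ties broken by reference id
    (lexicographic); fewer than n references returns them all.
    References sharing the query's id are skipped.
    """
    if n <= 0:
        return []
    candidates = [decide_pair(query, r) for r in refs if r.genome_id != query.genome_id]
    candidates.sort(key=lambda rec: (-(rec.pccd if not rec.undefined else -math.inf),
                                     rec.ref_id))
    out = []
    for rec in candidates[:n]:
        out.append(SieveRecord(rec.query_id, rec.ref_id, rec.pccd, rec.gsc_p,
                               sieved=True, rescued=True, undefined=rec.undefined))
    return out


def _check_unique(sigs: list[Signature], role: str) -> None:
    seen = set()
    for s in sigs:
        if s.genome_id in seen:
            raise InputError(f"duplicate {role} genome id: {s.genome_id!r}")
        seen.add(s.genome_id)


def sieve_all(
    queries: list[Signature],
    refs: list[Signature],
    n_rescue: int = DEFAULT_RESCUE_N,
) -> tuple[list[SieveRecord], dict]:
    """All queries against all references; one record per sieved pair
    plus rescue records, and a summary of totals.

    Self pairs (identical ids in both roles) are excluded.  Results are
    identical to evaluating :func:`decide_pair` sequentially over every
    pair; internally the PCCD matrix is computed blockwise.
    """
    _check_unique(queries, "query")
    _check_unique(refs, "reference")
    if not queries or not refs:
        return [], {"pairs_evaluated": 0, "pairs_sieved": 0,
                    "queries_rescued": 0, "rescue_records": 0}

    rid = [s.genome_id for s in refs]
    gr = np.array([s.gsc for s in refs])
    norm_r = [_normalized(s.zrf.values) for s in refs]
    rdef = np.array([v is not None for v in norm_r])
    Rn = np.stack([v if v is not None else np.zeros(len(s.zrf.values))
                   for v, s in zip(norm_r, refs)])

    records: list[SieveRecord] = []
    pairs_evaluated = 0
    pairs_sieved = 0
    queries_rescued = 0
    rescue_records = 0

    for q in queries:
        nq = _normalized(q.zrf.values)
        non_self = np.array([r != q.genome_id for r in rid])
        pairs_evaluated += int(non_self.sum())
        if nq is None:
            row = np.full(len(refs), math.nan)
            defined = np.zeros(len(refs), dtype=bool)
        else:
            row = np.clip(Rn @ nq, -1.0, 1.0)
            defined = rdef
        gscp = np.minimum(q.gsc, gr)
        hit = non_self & defined & (row >= gscp)
        emitted = 0
        for j in np.flatnonzero(hit):
            records.append(SieveRecord(q.genome_id, rid[j], float(row[j]),
                                       float(gscp[j]), sieved=True, rescued=False))
            emitted += 1
        pairs_sieved += emitted
        if emitted == 0 and n_rescue > 0:
            order = sorted(
                (j for j in range(len(refs)) if non_self[j]),
                key=lambda j: (-(row[j] if defined[j] else -math.inf), rid[j]),
            )[:n_rescue]
            if order:
                queries_rescued += 1
            for j in order:
                records.append(SieveRecord(
                    q.genome_id, rid[j],
                    float(row[j]) if defined[j] else math.nan,
                    float(gscp[j]), sieved=True, rescued=True,
                    undefined=not bool(defined[j]),
                ))
                rescue_records += 1

    summary = {
        "pairs_evaluated": pairs_evaluated,
        "pairs_sieved": pairs_sieved,
        "queries_rescued": queries_rescued,
        "rescue_records": rescue_records,
    }
    return records, summary
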