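"""Per-genome signature construction.

Pipeline: divide the concatenated genome with a half-overlapping sliding
window, compute fragment z-vectors, build the representative z-vector
(ZRF) by central-value averaging, derive the genome-specific cutoff
(GSC = Mean - SD - 0.01 over fragment-vs-ZRF PCCDs), floor it by the
length-specific cutoff LSC1, and re-fragment at 10 kb to refresh the
ZRF when the raw GSC falls at or below LSC2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationTable, lsc_values
from .errors import InputError, TooShortGenomeError
from .genome_io import Genome
from .tetra_core import ZVector, encode, pccd, zvalues_from_codes

MIN_GENOME_BP = 10_000
NO_DIVIDE_BELOW_BP = 40_000
EIGHT_FRAGMENT_MAX_BP = 800_000
LARGE_AVG_SEQ_BP = 200_000
LARGE_WINDOW_BP = 200_000
REFRAGMENT_L_BP = 10_000
BOUNDARY_EPSILON = 0.01


@dataclass(frozen=True)
class FragmentSet:
    """Half-open 0-based windows on the concatenated genome."""

    windows: tuple[tuple[int, int], ...]
    window_len_l_bp: int


@dataclass
class Signature:
    genome_id: str
    zrf: ZVector
    gsc: float
    lsc1: float
    lsc2: float
    restricted_by_lsc1: bool
    refragmented_10kb: bool
    n_fragments: int


def _windows(L: int, l: float) -> tuple[tuple[int, int], ...]:
    """Sliding windows of length l starting at multiples of l/2.

    Starts run while start < L; the final window is truncated at L and
    kept iff its length is at least l/2 (one-bp rounding slack for odd
    lengths).
    """
    half = l / 2.0
    out = []
    k = 0
    while k * half < L:
        s = int(round(k * half))
        e = min(int(round(k * half + l)), L)
        if e - s >= half - 1:
            out.append((s, e))
        k += 1
    return tuple(out)


def divide_genome(
    g: Genome,
    no_divide_below_bp: int = NO_DIVIDE_BELOW_BP,
    eight_fragment_max_bp: int = EIGHT_FRAGMENT_MAX_BP,
    large_window_bp: int = LARGE_WINDOW_BP,
) -> FragmentSet:
    """Window layout for a processed (concatenated) genome of length L.

    * L < 40 kb: a single window covering the genome.
    * 40 kb <= L <= 800 kb: l = L/4, giving exactly 8 windows.
    * L > 800 kb: l = L/4 if the average retained-sequence size exceeds
      200 kb (again 8 windows), otherwise l = 200 kb.
    """
    L = g.total_length_bp
    if L < MIN_GENOME_BP:
        raise TooShortGenomeError(
            f"genome {g.id!r}: {L} bp < {MIN_GENOME_BP} bp minimum; excluded from sieving"
        )
    if L < no_divide_below_bp:
        return FragmentSet(windows=((0, L),), window_len_l_bp=L)
    if L <= eight_fragment_max_bp or g.avg_seq_size_bp > LARGE_AVG_SEQ_BP:
        l = L / 4.0
    else:
        l = float(large_window_bp)
    return FragmentSet(windows=_windows(L, l), window_len_l_bp=int(round(l)))


def compute_zrf(zmatrix: list[ZVector]) -> ZVector:
    """Representative z-vector by per-tetranucleotide central averaging.

    For each of the 136 channels independently the fragment z-values are
    sorted and the middle 3 (odd count >= 3) or middle 4 (even count
    >= 4) are averaged.  One fragment: returned verbatim; two fragments:
    mean of both (degenerate case).
    """
    if not zmatrix:
        raise InputError("compute_zrf needs at least one fragment vector")
    n = len(zmatrix)
    total = sum(z.source_length_bp for z in zmatrix)
    if n == 1:
        return ZVector(values=zmatrix[0].values.copy(), source_length_bp=total)
    m = np.sort(np.stack([z.values for z in zmatrix]), axis=0)
    if n == 2:
        central = m
    elif n % 2 == 1:
        central = m[n // 2 - 1 : n // 2 + 2]
    else:
        central = m[n // 2 - 2 : n // 2 + 2]
    return ZVector(values=central.mean(axis=0), source_length_bp=total)


def compute_gsc(
    pccds: list[float],
    legacy: bool = False,
    epsilon: float = BOUNDARY_EPSILON,
) -> float:
    """Genome-specific cutoff from intragenomic fragment-vs-ZRF PCCDs.

    Default mode: Mean - SD - epsilon (epsilon covers boundary effect).
    Legacy mode: Mean - 2*SD.  SD is the sample (n-1) standard
    deviation; a single fragment uses SD = 0.
    """
    if not pccds:
        raise InputError("compute_gsc needs at least one PCCD")
    arr = np.asarray(pccds, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    if legacy:
        return mean - 2.0 * sd
    return mean - sd - epsilon


def build_signature(
    g: Genome,
    table: CalibrationTable,
    legacy_gsc: bool = False,
    refragment_l_bp: int = REFRAGMENT_L_BP,
    epsilon: float = BOUNDARY_EPSILON,
) -> Signature:
    """Full signature pipeline for a pre-processed, concatenated genome.

    If the raw GSC is below LSC1 it is forced up to LSC1
    (``restricted_by_lsc1``).  If the raw GSC is at or below LSC2 the
    genome is re-fragmented with a 10-kb window and only the ZRF is
    recomputed (``refragmented_10kb``); the stored GSC keeps its
    (possibly restricted) value.
    """
    frags = divide_genome(g)
    codes = encode(g.concatenated())
    zs = [zvalues_from_codes(codes, s, e) for s, e in frags.windows]
    zrf = compute_zrf(zs)
    raw_gsc = compute_gsc([pccd(z, zrf) for z in zs], legacy=legacy_gsc, epsilon=epsilon)
    lsc1, lsc2 = lsc_values(g.total_length_bp, table, epsilon=epsilon)

    restricted = raw_gsc < lsc1
    gsc = lsc1 if restricted else raw_gsc
    refragment = raw_gsc <= lsc2
    n_fragments = len(frags.windows)
    if refragment:
        win10 = _windows(g.total_length_bp, float(refragment_l_bp))
        zs10 = [zvalues_from_codes(codes, s, e) for s, e in win10]
        zrf = compute_zrf(zs10)
        n_fragments = len(win10)
    return Signature(
        genome_id=g.id,
        zrf=zrf,
        gsc=gsc,
        lsc1=lsc1,
        lsc2=lsc2,
        restricted_by_lsc1=restricted,
        refragmented_10kb=refragment,
        n_fragments=n_fragments,
    )
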