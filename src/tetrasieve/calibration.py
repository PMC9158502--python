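"""Length-specific cutoff (LSC) calibration.

The sieve floors each genome-specific cutoff with length-specific
cutoffs derived from an empirical distribution of intraspecific PCCDs
at a given genome size (binned in kb, capped at 200):

    LSC1 = mean_intra - sd_intra - 0.01
    LSC2 = mean_intra - 2 * sd_intra

The original empirical tables are not printed anywhere, so this module
both serves user-supplied tables (TSV) and reconstructs one by sampling
pairs of heavily overlapping extracts of the same genome — the same
intraspecific proxy used by the pair simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CalibrationError, InputError, ValidationError
from .tetra_core import pccd, zvalues_from_codes, encode

MAX_BIN_KB = 200
DEFAULT_MIN_SAMPLES = 100
_COLUMNS = ["kb", "mean_intra", "sd_intra", "n_samples"]


@dataclass(frozen=True)
class CalibrationRow:
    kb: int
    mean_intra: float
    sd_intra: float
    n_samples: int


@dataclass(frozen=True)
class CalibrationTable:
    rows: tuple[CalibrationRow, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("calibration table has no rows")
        bins = [r.kb for r in self.rows]
        if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
            raise ValidationError("calibration bins must be strictly increasing")
        if bins[-1] > MAX_BIN_KB:
            raise ValidationError(f"calibration bins must not exceed {MAX_BIN_KB} kb")
        for r in self.rows:
            if not (-1.0 < r.mean_intra <= 1.0) or r.sd_intra < 0:
                raise ValidationError(f"calibration row out of range: {r}")

    def validate_samples(self, min_samples: int = DEFAULT_MIN_SAMPLES) -> None:
        for r in self.rows:
            if r.n_samples < min_samples:
                raise ValidationError(
                    f"bin {r.kb} kb has {r.n_samples} samples < required {min_samples}"
                )

    @property
    def bins_kb(self) -> list[int]:
        return [r.kb for r in self.rows]


def lsc_values(
    L_bp: int,
    table: CalibrationTable,
    epsilon: float = 0.01,
    tol_kb: int = 10,
) -> tuple[float, float]:
    """(LSC1, LSC2) for a genome of L_bp total length.

    The genome size in kb is capped at 200 and snapped to the nearest
    table bin; no bin within ``tol_kb`` raises a calibration error.
    """
    if L_bp < 10_000:
        raise InputError(f"genome of {L_bp} bp below 10 kb minimum")
    target = min(round(L_bp / 1000), MAX_BIN_KB)
    best = min(table.rows, key=lambda r: (abs(r.kb - target), r.kb))
    if abs(best.kb - target) > tol_kb:
        raise CalibrationError(
            f"no calibration bin within {tol_kb} kb of {target} kb"
        )
    lsc1 = best.mean_intra - best.sd_intra - epsilon
    lsc2 = best.mean_intra - 2.0 * best.sd_intra
    return lsc1, lsc2


def calibrate(
    genomes: list,
    bins_kb: list[int],
    n_pairs_per_bin: int,
    seed: int,
    min_overlap: float = 0.7,
) -> CalibrationTable:
    """Build a table from intraspecific proxy pairs.

    For each bin two extracts of exactly ``kb`` kilobases are drawn from
    a randomly chosen (sufficiently long) genome with mutual overlap
    uniform in [min_overlap, 1]; the mean and sample SD of the PCCDs
    between their z-vectors over ``n_pairs_per_bin`` draws form the row.
    Deterministic for a fixed seed.
    """
    if n_pairs_per_bin < 2:
        raise InputError("need at least 2 pairs per bin")
    if any(b2 <= b1 for b1, b2 in zip(bins_kb, bins_kb[1:])):
        raise ValidationError("bins must be strictly increasing")
    rng = np.random.default_rng(seed)
    encoded = [(g, encode(g.concatenated())) for g in genomes]
    rows = []
    for kb in bins_kb:
        size = kb * 1000
        eligible = [(g, c) for g, c in encoded if g.total_length_bp >= size]
        if not eligible:
            raise CalibrationError(f"no genome long enough for the {kb} kb bin")
        vals = np.empty(n_pairs_per_bin)
        for i in range(n_pairs_per_bin):
            g, codes = eligible[int(rng.integers(len(eligible)))]
            L = g.total_length_bp
            frac = float(rng.uniform(min_overlap, 1.0))
            o = int(round(frac * size))
            o = max(o, 2 * size - L)  # extracts must fit inside the genome
            union = 2 * size - o
            u0 = int(rng.integers(0, L - union + 1))
            z1 = zvalues_from_codes(codes, u0, u0 + size)
            z2 = zvalues_from_codes(codes, u0 + union - size, u0 + union)
            vals[i] = pccd(z1, z2)
        rows.append(
            CalibrationRow(
                kb=kb,
                mean_intra=float(vals.mean()),
                sd_intra=float(vals.std(ddof=1)),
                n_samples=n_pairs_per_bin,
            )
        )
    prov = f"calibrate(seed={seed}, pairs_per_bin={n_pairs_per_bin}, genomes={len(genomes)})"
    return CalibrationTable(rows=tuple(rows), provenance=prov)


def save_table(table: CalibrationTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if table.provenance:
            fh.write(f"# provenance: {table.provenance}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in table.rows:
            fh.write(f"{r.kb}\t{r.mean_intra!r}\t{r.sd_intra!r}\t{r.n_samples}\n")


def load_table(path: str | Path) -> CalibrationTable:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such calibration table: {path}")
    provenance = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            provenance = first[len("# provenance:"):].strip()
    try:
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot parse calibration table {path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"calibration table {path} missing columns: {missing}")
    rows = tuple(
        CalibrationRow(
            kb=int(r.kb),
            mean_intra=float(r.mean_intra),
            sd_intra=float(r.sd_intra),
            n_samples=int(r.n_samples),
        )
        for r in df.itertuples()
    )
    return CalibrationTable(rows=rows, provenance=provenance)


def load_default_table() -> CalibrationTable:
    """The packaged table, built from seeded synthetic genomes.

    Regenerate with the CLI: ``tetrasieve calibrate`` (see the file's
    provenance header for the exact parameters).
    """
    ref = resources.files("tetrasieve").joinpath("data/default_lsc.tsv")
    with resources.as_file(ref) as path:
        return load_table(path)
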