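"""Seeded generators for genomes, genome pairs, and benchmark metrics.

Genomes are sampled from a block mixture of distinct tetranucleotide
(memory-3) Markov models, which gives them a strong, internally
consistent tetranucleotide signature (deviating from the memory-2
expectation underlying the z-values) with controllable heterogeneity.
Pairs are built by extracting a genome twice with an exact target
overlap, so intraspecific pairs realize a requested PSG; extracts from
different parent genomes serve as interspecific pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from numba import njit

from .errors import InputError, ValidationError
from .genome_io import Genome
from .sieve_engine import SieveRecord
from .tetra_core import codes_to_seq

DEFAULT_BLOCK_LEN_BP = 25_000
DEFAULT_CONCENTRATION = 0.5


@dataclass(frozen=True)
class SimPairSpec:
    """Recipe for one simulated genome pair."""

    genome_length_bp: int
    psg_target_pct: float
    completeness_q_pct: float
    completeness_r_pct: float
    label: str  # "intraspecific" | "interspecific"
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.psg_target_pct <= 100.0):
            raise ValidationError("psg_target_pct must be in [0, 100]")
        for c in (self.completeness_q_pct, self.completeness_r_pct):
            if not (0.0 < c <= 100.0):
                raise ValidationError("completeness must be in (0, 100]")
        if self.label not in ("intraspecific", "interspecific"):
            raise ValidationError(f"unknown label {self.label!r}")


@njit(cache=False)
def _markov_block(cum: np.ndarray, u: np.ndarray, state: int):  # pragma: no cover
    n = u.size
    out = np.empty(n, dtype=np.int8)
    s = state
    for i in range(n):
        r = u[i]
        row = cum[s]
        d = 0
        while d < 3 and r > row[d]:
            d += 1
        out[i] = d
        s = ((s << 2) | d) & 63
    return out, s


def markov_sequence(transitions: np.ndarray, length: int, rng: np.random.Generator,
                    state: int | None = None) -> str:
    """Sequence from a memory-3 Markov chain given a (64, 4) transition matrix."""
    cum = np.cumsum(np.asarray(transitions, dtype=np.float64), axis=1)
    if state is None:
        state = int(rng.integers(64))
    codes, _ = _markov_block(cum, rng.random(length), state)
    return codes_to_seq(codes)


def random_transitions(rng: np.random.Generator,
                       concentration: float = DEFAULT_CONCENTRATION) -> np.ndarray:
    """Random (64, 4) memory-3 transition matrix, Dirichlet per context."""
    return rng.dirichlet(np.full(4, concentration), size=64)


def simulate_genome(
    length_bp: int,
    n_components: int = 1,
    seed: int = 0,
    block_len_bp: int = DEFAULT_BLOCK_LEN_BP,
    concentration: float = DEFAULT_CONCENTRATION,
    id: str | None = None,
) -> Genome:
    """Single-sequence genome from a block mixture of Markov models.

    Blocks of ``block_len_bp`` cycle round-robin through
    ``n_components`` independently drawn memory-3 models, giving
    intra-genomic tetranucleotide heterogeneity that grows with the
    number (and separation) of components.  Deterministic per seed.
    """
    if length_bp < 10_000:
        raise InputError("simulated genomes must be at least 10 kb")
    if n_components < 1:
        raise InputError("n_components must be >= 1")
    rng = np.random.default_rng(seed)
    cums = [np.cumsum(random_transitions(rng, concentration), axis=1)
            for _ in range(n_components)]
    u = rng.random(length_bp)
    codes = np.empty(length_bp, dtype=np.int8)
    state = int(rng.integers(64))
    pos = 0
    block = 0
    while pos < length_bp:
        end = min(pos + block_len_bp, length_bp)
        seg, state = _markov_block(cums[block % n_components], u[pos:end], state)
        codes[pos:end] = seg
        pos = end
        block += 1
    gid = id if id is not None else f"sim-{seed}"
    seq = codes_to_seq(codes)
    return Genome(id=gid, sequences=((gid, seq),),
                  total_length_bp=length_bp, avg_seq_size_bp=float(length_bp))


def extract_pair(g: Genome, spec: SimPairSpec) -> tuple[Genome, Genome, float]:
    """Two extracts of ``g`` realizing the spec's PSG target exactly.

    Extract lengths are ``completeness * L``; the overlap
    ``o = psg_target * (len1 + len2) / 200`` is placed uniformly at
    random (left/right roles swapped at random).  The realized PSG is
    recomputed from the placed coordinates with the interval-union
    definition and must land within 0.5 points of the target.
    """
    L = g.total_length_bp
    rng = np.random.default_rng(spec.seed)
    len1 = int(round(L * spec.completeness_q_pct / 100.0))
    len2 = int(round(L * spec.completeness_r_pct / 100.0))
    if min(len1, len2) < 1:
        raise ValidationError("completeness too small: empty extract")
    o = int(round(spec.psg_target_pct * (len1 + len2) / 200.0))
    if o > min(len1, len2):
        raise ValidationError(
            f"infeasible spec: overlap {o} bp exceeds shorter extract "
            f"({min(len1, len2)} bp); lower the PSG target or raise completeness"
        )
    union = len1 + len2 - o
    if union > L:
        raise ValidationError(
            f"infeasible spec: extracts span {union} bp > genome length {L} bp; "
            f"lower completeness or raise the PSG target"
        )
    u0 = int(rng.integers(0, L - union + 1))
    if rng.random() < 0.5:
        iv1 = (u0, u0 + len1)
        iv2 = (u0 + union - len2, u0 + union)
    else:
        iv2 = (u0, u0 + len2)
        iv1 = (u0 + union - len1, u0 + union)
    seq = g.concatenated()
    gq = Genome(id=f"{g.id}.q", sequences=((f"{g.id}.q", seq[iv1[0]:iv1[1]]),),
                total_length_bp=len1, avg_seq_size_bp=float(len1))
    gr = Genome(id=f"{g.id}.r", sequences=((f"{g.id}.r", seq[iv2[0]:iv2[1]]),),
                total_length_bp=len2, avg_seq_size_bp=float(len2))
    o_real = max(0, min(iv1[1], iv2[1]) - max(iv1[0], iv2[0]))
    realized = 100.0 * 2 * o_real / (len1 + len2)
    if abs(realized - spec.psg_target_pct) > 0.5:
        raise ValidationError(
            f"realized PSG {realized:.3f} deviates from target {spec.psg_target_pct}"
        )
    return gq, gr, realized


def feasible_grid(
    psg_targets: Iterable[float],
    completeness_steps: Iterable[float],
) -> list[tuple[float, float]]:
    """(psg, completeness) cells where two equal-completeness extracts fit.

    Feasibility for equal completeness c (fraction of L) and PSG p:
    union = c*L*(2 - p/100) must not exceed L.
    """
    out = []
    for p in psg_targets:
        for c in completeness_steps:
            if c / 100.0 * (2.0 - p / 100.0) <= 1.0 + 1e-12:
                out.append((p, c))
    return out


def benchmark(
    sieve_output: list[SieveRecord],
    truth: Mapping[tuple[str, str], str] | Iterable[tuple[str, str, str]],
) -> dict:
    """Sensitivity/specificity of sieve output against truth labels.

    ``truth`` maps (query_id, ref_id) to "intraspecific" or
    "interspecific"; each pair may appear once.  Sensitivity = sieved
    intraspecific / all intraspecific; specificity = unsieved
    interspecific / all interspecific.  Rescued records count as
    sieved.
    """
    if isinstance(truth, Mapping):
        labels = dict(truth)
    else:
        labels = {}
        for q, r, lab in truth:
            if (q, r) in labels:
                raise ValidationError(f"duplicate truth pair ({q!r}, {r!r})")
            labels[(q, r)] = lab
    for lab in labels.values():
        if lab not in ("intraspecific", "interspecific"):
            raise ValidationError(f"unknown truth label {lab!r}")
    sieved = set()
    for rec in sieve_output:
        if not rec.sieved:
            continue
        key = (rec.query_id, rec.ref_id)
        if key not in labels:
            raise ValidationError(f"sieved pair {key} absent from truth labels")
        sieved.add(key)
    n_intra = sum(1 for lab in labels.values() if lab == "intraspecific")
    n_inter = len(labels) - n_intra
    intra_sieved = sum(1 for k in sieved if labels[k] == "intraspecific")
    inter_sieved = len(sieved) - intra_sieved
    return {
        "n_intra": n_intra,
        "n_inter": n_inter,
        "n_intra_sieved": intra_sieved,
        "n_inter_sieved": inter_sieved,
        "sensitivity_pct": 100.0 * intra_sieved / n_intra if n_intra else float("nan"),
        "specificity_pct": (100.0 * (n_inter - inter_sieved) / n_inter
                            if n_inter else float("nan")),
        "sieved_fraction_pct": 100.0 * len(sieved) / len(labels) if labels else 0.0,
    }
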