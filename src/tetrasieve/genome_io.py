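"""Genome loading and pre-processing.

Reads FASTA assemblies, discards sequences shorter than a minimum length
(default 1 kb), tracks total and average retained-sequence size, and
concatenates multi-sequence (draft) genomes into a single sequence after
ordering the pieces by a naive-Bayes posterior score under a
tetranucleotide Markov model trained on the whole genome.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import EmptyGenomeError, InputError
from . import tetra_core

DEFAULT_MIN_SEQ_LEN = 1000


@dataclass(frozen=True)
class Genome:
    """A named set of nucleotide sequences plus derived metadata."""

    id: str
    sequences: tuple[tuple[str, str], ...]
    total_length_bp: int
    avg_seq_size_bp: float

    @classmethod
    def from_sequences(
        cls,
        id: str,
        sequences: list[tuple[str, str]],
        min_seq_len: int = DEFAULT_MIN_SEQ_LEN,
    ) -> "Genome":
        """Build a genome applying the short-sequence filter.

        Raises
        ------
        EmptyGenomeError
            If no sequence reaches ``min_seq_len``.
        """
        kept = [(n, s.upper()) for n, s in sequences if len(s) >= min_seq_len]
        if not kept:
            raise EmptyGenomeError(
                f"genome {id!r}: no sequence of >= {min_seq_len} bp; cannot be sieved"
            )
        total = sum(len(s) for _, s in kept)
        return cls(
            id=id,
            sequences=tuple(kept),
            total_length_bp=total,
            avg_seq_size_bp=total / len(kept),
        )

    def concatenated(self) -> str:
        return "".join(s for _, s in self.sequences)


def load_genome(
    path: str | Path,
    id: str | None = None,
    min_seq_len: int = DEFAULT_MIN_SEQ_LEN,
) -> Genome:
    """Load a FASTA genome (plain or gzip) applying the length filter.

    ``id`` defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    try:
        with opener(path, "rt") as fh:
            records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise InputError(f"no FASTA records in {path}")
    if id is None:
        id = path.name
        for suff in (".gz", ".fasta", ".fa", ".fna"):
            if id.endswith(suff):
                id = id[: -len(suff)]
    return Genome.from_sequences(id, records, min_seq_len=min_seq_len)


def _markov_scores(g: Genome) -> list[float]:
    """Length-normalized log-likelihood of each sequence under a
    tetranucleotide (memory-3) Markov model trained on the whole genome.

    Transition probabilities use add-one pseudo-counts:
    P(d | abc) = (n4(abcd) + 1) / (n3(abc) + 4).  Windows with non-ACGT
    characters are skipped; a sequence with no valid window scores -inf.
    """
    codes = [tetra_core.encode(s) for _, s in g.sequences]
    n4 = np.zeros(256, dtype=np.int64)
    n3 = np.zeros(64, dtype=np.int64)
    for c in codes:
        n4 += _forward_counts(c, 4)
        n3 += _forward_counts(c, 3)
    logp = np.log(n4 + 1.0) - np.log(n3[np.arange(256) >> 2] + 4.0)
    scores = []
    for c in codes:
        idx, ok = _forward_index(c, 4)
        if not ok.any():
            scores.append(-math.inf)
        else:
            scores.append(float(logp[idx[ok]].mean()))
    return scores


def _forward_index(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    valid = codes >= 0
    safe = np.where(valid, codes, 0).astype(np.int64)
    idx = safe[: n - k + 1].copy()
    ok = valid[: n - k + 1].copy()
    for j in range(1, k):
        idx <<= 2
        idx |= safe[j : n - k + 1 + j]
        ok &= valid[j : n - k + 1 + j]
    return idx, ok


def _forward_counts(codes: np.ndarray, k: int) -> np.ndarray:
    idx, ok = _forward_index(codes, k)
    return np.bincount(idx[ok], minlength=4**k)


def bayes_concatenate(g: Genome, descending: bool = True) -> Genome:
    """Concatenate a genome's sequences ordered by naive-Bayes posterior.

    Sequences are scored by mean per-position log-probability under the
    whole-genome tetranucleotide Markov model and sorted (descending by
    default: most genome-typical first); ties keep input order.  A
    single-sequence genome is returned unchanged.
    """
    if len(g.sequences) == 1:
        return g
    scores = _markov_scores(g)
    order = sorted(
        range(len(scores)),
        key=(lambda i: (-scores[i], i)) if descending else (lambda i: (scores[i], i)),
    )
    concat = "".join(g.sequences[i][1] for i in order)
    return Genome(
        id=g.id,
        sequences=((g.id, concat),),
        total_length_bp=g.total_length_bp,
        avg_seq_size_bp=g.avg_seq_size_bp,
    )
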