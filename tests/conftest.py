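from __future__ import annotations

import numpy as np
import pytest

from tetrasieve.calibration import CalibrationRow, CalibrationTable, load_default_table
from tetrasieve.genome_io import Genome
from tetrasieve.synthetic_data import simulate_genome


def random_dna(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def make_genome(seq: str, id: str = "g") -> Genome:
    return Genome(id=id, sequences=((id, seq),),
                  total_length_bp=len(seq), avg_seq_size_bp=float(len(seq)))


@pytest.fixture(scope="session")
def flat_table() -> CalibrationTable:
    """Permissive table: identical bins, low cutoffs, never restricts."""
    rows = tuple(CalibrationRow(kb=kb, mean_intra=0.5, sd_intra=0.1, n_samples=100)
                 for kb in range(10, 201, 10))
    return CalibrationTable(rows=rows, provenance="test fixture")


@pytest.fixture(scope="session")
def default_table() -> CalibrationTable:
    return load_default_table()


@pytest.fixture(scope="session")
def sim_genome_1mb() -> Genome:
    return simulate_genome(1_000_000, n_components=2, seed=5)
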