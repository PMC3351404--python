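from __future__ import annotations

import numpy as np
import pytest

import caryogeo
from caryogeo.seq_data import Alignment, read_locality_table


@pytest.fixture(scope="session")
def locality_table():
    """The bundled Carychium sampling-locality table (two species)."""
    return read_locality_table(caryogeo.example_locality_table_path())


@pytest.fixture
def quartet():
    """The canonical 4-sequence, 3-site worked example (S=3, kbar=10/6)."""
    return Alignment.from_records(
        [("a", "AAA"), ("b", "AAT"), ("c", "ATT"), ("d", "TTT")])


def random_alignment(rng: np.random.Generator, n: int, length: int,
                     n_var: int | None = None, missing: float = 0.0
                     ) -> Alignment:
    """A random alignment with a controllable number of variable sites."""
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=length)
    mat = np.tile(ref, (n, 1))
    n_var = length // 3 if n_var is None else n_var
    var_cols = rng.choice(length, size=min(n_var, length), replace=False)
    for col in var_cols:
        carriers = rng.random(n) < rng.uniform(0.1, 0.9)
        mat[carriers, col] = (mat[carriers, col] + rng.integers(1, 4)) % 4
    seqs = ["".join(bases[row]) for row in mat]
    if missing > 0:
        seqs = [
            "".join("N" if rng.random() < missing else c for c in s)
            for s in seqs
        ]
    return Alignment.from_records([(f"s{i}", s) for i, s in enumerate(seqs)])
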