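import numpy as np
import pandas as pd
import pytest

from specnet.io_tables import SpectralCountTable


@pytest.fixture
def groups_3v3() -> dict[str, str]:
    return {
        "C1": "control", "C2": "control", "C3": "control",
        "I1": "injured", "I2": "injured", "I3": "injured",
    }


@pytest.fixture
def small_table(groups_3v3) -> SpectralCountTable:
    counts = pd.DataFrame(
        {
            "C1": [5, 0, 12, 3],
            "C2": [6, 1, 10, 2],
            "C3": [4, 0, 11, 4],
            "I1": [20, 7, 3, 0],
            "I2": [25, 9, 2, 1],
            "I3": [22, 8, 4, 0],
        },
        index=["P1", "P2", "P3", "P4"],
        dtype=np.int64,
    )
    unique = (counts > 0).astype(np.int64) * 3
    return SpectralCountTable(counts=counts, groups=groups_3v3, unique_peptides=unique)


def random_count_table(rng: np.random.Generator, n_proteins: int = 30,
                       n_per_group: int = 3) -> SpectralCountTable:
    samples = [f"C{i}" for i in range(n_per_group)] + [f"I{i}" for i in range(n_per_group)]
    counts = pd.DataFrame(
        rng.poisson(8.0, size=(n_proteins, 2 * n_per_group)) + 1,
        index=[f"P{i:04d}" for i in range(n_proteins)],
        columns=samples,
    )
    groups = {s: ("control" if s.startswith("C") else "injured") for s in samples}
    return SpectralCountTable(counts=counts, groups=groups)
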