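import numpy as np
import pandas as pd
import pytest

from dualomics.simulate import SimConfig, simulate_all


@pytest.fixture
def small_counts() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4"],
            "length": [1000, 500, 2000, 800],
            "count_1": [100, 0, 400, 5],
            "count_2": [300, 50, 380, 0],
        }
    )


@pytest.fixture
def peptide_table() -> pd.DataFrame:
    rows = []
    for pid, ratios, shared in [
        ("pA", [2.0, 8.0], [0, 0]),
        ("pB", [1.0, 1.0, 1.0], [0, 0, 0]),
        ("pC", [0.5, 0.4, 0.45, 0.5], [0, 0, 0, 1]),
        ("pD", [3.0], [0]),
        ("pE", [1.5, 1.5], [1, 1]),  # all shared: dropped
    ]:
        for j, (r, s) in enumerate(zip(ratios, shared)):
            rows.append((pid, f"{pid}_{j}", r, s))
    return pd.DataFrame(rows, columns=["protein_id", "peptide_id", "ratio", "is_shared"])


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """One default-scale simulation shared across tests."""
    out = tmp_path_factory.mktemp("sim")
    return simulate_all(SimConfig(seed=20150619), out), out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(11402)
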