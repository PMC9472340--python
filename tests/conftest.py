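import numpy as np
import pandas as pd
import pytest

from homoeokit.config import AnalysisConfig
from homoeokit.simulate import SimulationParams, simulate_all


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated dataset shared across tests (ground truth known)."""
    params = SimulationParams(
        n_pairs=80, n_chrom_pairs=2, cytosines_per_region=20, seed=7
    )
    return simulate_all(params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_matrix(counts: dict, groups: dict):
    """Build a tiny ExpressionMatrix from {gene: {sample: count}} and group map."""
    from homoeokit.core import ExpressionMatrix

    counts_df = pd.DataFrame(counts).T
    rows = []
    for sample in counts_df.columns:
        group, role, rep = groups[sample]
        rows.append((sample, group, role, rep, "t"))
    sheet = pd.DataFrame(
        rows, columns=["sample_id", "group", "role", "replicate", "tissue"]
    ).set_index("sample_id")
    return ExpressionMatrix(counts=counts_df.astype(int), samples=sheet)
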