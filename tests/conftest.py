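import numpy as np
import pandas as pd
import pytest

from viroclean.abundance import AbundanceMatrix
from viroclean.synthetic import SimConfig, simulate_dataset, strain_comparisons


def toy_matrix(rpkm: dict, meta_rows: list[tuple[str, str, str]]) -> AbundanceMatrix:
    """Build a small AbundanceMatrix from {votu: {sample: value}} + (id, study, role)."""
    meta = pd.DataFrame(
        [{"sample_id": s, "study": st, "role": r} for s, st, r in meta_rows]
    ).set_index("sample_id")
    df = pd.DataFrame(rpkm).T.astype(float)
    df = df.reindex(columns=meta.index).fillna(0.0)
    df.index.name = "votu_id"
    return AbundanceMatrix(df, meta)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-design simulated dataset, shared across tests."""
    return simulate_dataset(SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_comparisons(default_dataset):
    return strain_comparisons(default_dataset, scope="own_study")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
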