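import numpy as np
import pandas as pd
import pytest

from monoflame import synthetic


@pytest.fixture(scope="session")
def full_design() -> pd.DataFrame:
    """The 36-sample two-arm kinetic design."""
    return synthetic.make_design()


@pytest.fixture(scope="session")
def small_sim(full_design):
    """A small simulated data set shared across read-only tests."""
    counts, truth = synthetic.simulate_counts(
        full_design, synthetic.CountSimParams(n_genes=2000), seed=11
    )
    return counts, truth


@pytest.fixture()
def two_group_design() -> pd.DataFrame:
    """Minimal 3 vs 3 design at one time point."""
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(6)],
            "donor": [f"d{i}" for i in range(6)],
            "arm": ["resolving"] * 3 + ["persistent"] * 3,
            "time_h": [24.0] * 6,
        }
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
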