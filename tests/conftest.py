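import numpy as np
import pandas as pd
import pytest

from microidx import FeatureTable, SimulationConfig, simulate_reference_cohort


@pytest.fixture
def toy_counts() -> FeatureTable:
    """4 samples x 3 features count table with hand-checkable structure."""
    data = pd.DataFrame(
        {
            "f1": [10, 9, 2, 1],
            "f2": [5, 5, 5, 1],
            "f3": [3, 3, 3, 3],
        },
        index=["a1", "a2", "b1", "b2"],
    )
    return FeatureTable(data, "counts")


@pytest.fixture
def toy_labels() -> pd.Series:
    return pd.Series(["A", "A", "B", "B"], index=["a1", "a2", "b1", "b2"])


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated two-group cohort reused across read-only tests."""
    cfg = SimulationConfig(
        n_samples_per_group=25,
        n_features=120,
        n_pos_effect=15,
        n_neg_effect=10,
        effect_log2fc=2.0,
        depth_mean=5000,
        seed=11,
    )
    return cfg, *simulate_reference_cohort(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
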