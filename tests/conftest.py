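import numpy as np
import pandas as pd
import pytest

from cnaware import DesignSpec, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_design() -> DesignSpec:
    ids = [f"n{i}" for i in range(3)] + [f"t{i}" for i in range(3)]
    return DesignSpec(
        pd.DataFrame(
            {"condition": [0, 0, 0, 1, 1, 1]}, index=pd.Index(ids, name="sample_id")
        )
    )


@pytest.fixture(scope="session")
def mixed_dataset():
    """Moderate simulated dataset with DSG/DIG/nonDEG classes (strong CN)."""
    cfg = SimConfig(
        n_genes=400,
        n_per_condition=12,
        class_proportions={"DSG": 0.1, "DIG": 0.3, "DCG": 0.0, "nonDEG": 0.6},
        seed=3,
    )
    return simulate_dataset(cfg, rng=np.random.default_rng(9))


@pytest.fixture(scope="session")
def all_class_dataset():
    """Dataset containing all four dosage classes (strong CN signal)."""
    cfg = SimConfig(
        n_genes=600,
        n_per_condition=20,
        class_proportions={"DSG": 0.15, "DIG": 0.25, "DCG": 0.15, "nonDEG": 0.45},
        seed=4,
    )
    return simulate_dataset(cfg, rng=np.random.default_rng(21))
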