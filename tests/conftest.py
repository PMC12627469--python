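import warnings

import numpy as np
import pytest

from paincontrol.synthetic import GeneratorConfig, ScheduleConfig, simulate_dataset

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """3-subject precision-change cohort with known generating values."""
    cfg = GeneratorConfig(
        model="precision_change_dynamic",
        n_subjects=3,
        seed=7,
        group_params={
            "alpha": 0.74,
            "tau0_C": 5.0,
            "tau0_P": 10.0,
            "tau1": 4.48,
            "h": 0.0,
        },
    )
    data, params = simulate_dataset(cfg, ScheduleConfig(seed=7))
    return data, params, cfg


@pytest.fixture(scope="session")
def null_cohort():
    """2-subject habituation-only cohort (fast fits)."""
    cfg = GeneratorConfig(
        model="null_hab",
        n_subjects=2,
        seed=3,
        group_params={"noise": 6.0, "h": (0.0, 0.3)},
    )
    data, params = simulate_dataset(cfg, ScheduleConfig(seed=3))
    return data, params, cfg
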