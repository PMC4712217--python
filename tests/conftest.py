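import numpy as np
import pytest

from panelmix import cohort


@pytest.fixture(scope="session")
def study_config():
    """Study-calibrated generator configuration (no missingness)."""
    return cohort.default_study_config()


@pytest.fixture(scope="session")
def study_sim(study_config):
    """One study-sized simulated panel (n = 923 + 390), complete data."""
    return cohort.simulate_panel(study_config, seed=20260921)


@pytest.fixture(scope="session")
def small_sim():
    """A small fast panel with 2% MCAR holes for I/O and imputation tests."""
    cfg = cohort.default_study_config(missing_rate=0.02)
    cfg.n_per_cohort = (250, 120)
    return cohort.simulate_panel(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
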