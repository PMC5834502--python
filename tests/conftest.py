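import numpy as np
import pytest

from thzcoag.cohort import CohortConfig


@pytest.fixture(scope="session")
def noiseless_water_config() -> CohortConfig:
    """One uncoagulated pure-water subject, no RBC effect, no noise."""
    cfg = CohortConfig(n_uncoagulated=1, n_early_coagulated=0,
                       rbc_coeff=0.0, subject_sigma=0.0)
    return cfg.model_copy(update={
        "instrument": cfg.instrument.model_copy(update={"peak_dynamic_range_db": None})})


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A small mixed cohort for fast pipeline-level tests."""
    return CohortConfig(n_uncoagulated=5, n_early_coagulated=5, n_thrombus=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180302)
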