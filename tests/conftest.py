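import numpy as np
import pytest

from mcidi import PipelineConfig, SyntheticConfig, draw_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """40 subjects, 30 features: fast but structurally complete cohort."""
    cfg = SyntheticConfig(
        n_subjects=40,
        n_features=30,
        frac_state_only=0.4,
        frac_state_mmse=0.2,
        seed=11,
    )
    return draw_cohort(cfg)


@pytest.fixture(scope="session")
def fast_config():
    """Pipeline settings cut down for unit-test speed (not study conditions)."""
    return PipelineConfig(n_repeats=2, n_penalties=20, lasso_cv_folds=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
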