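import numpy as np
import pytest

import nirsnet as nn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """A fast cohort spec: fewer/shorter recordings at 10 Hz.

    Correlation structure lives in the 0.01-0.1 Hz band, far below either
    Nyquist, so lowering the sampling rate changes runtime, not statistics.
    """
    return nn.CohortSpec(
        n_subjects=5,
        sampling_rate_hz=10.0,
        duration_s=240.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return nn.gen_cohort(small_spec)


@pytest.fixture(scope="session")
def fast_preprocess():
    """Preprocess settings matched to the short test recordings."""
    return nn.PreprocessConfig(discard_initial_s=30.0, keep_window_s=180.0)
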