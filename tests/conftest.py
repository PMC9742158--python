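import numpy as np
import pytest

from t1aniso.presets import scenario_3t, scenario_7t

SMALL = dict(grid_shape=(20, 20, 10), n_dirs_per_shell=32, n_b0=4)


@pytest.fixture(scope="session")
def clean_3t():
    """Noise-free, jitter-free single-subject 3 T scenario."""
    return scenario_3t(
        snr_b0=np.inf, snr_ir=np.inf, subject_t1_sd=0.0, subject_amp_cv=0.0,
        n_subjects=1, **SMALL,
    )


@pytest.fixture(scope="session")
def clean_7t():
    return scenario_7t(
        snr_b0=np.inf, snr_ir=np.inf, subject_t1_sd=0.0, subject_amp_cv=0.0,
        n_subjects=1, **SMALL,
    )


@pytest.fixture(scope="session")
def noisy_3t():
    """Default-noise small 3 T scenario (3 subjects)."""
    return scenario_3t(n_subjects=3, **SMALL)
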