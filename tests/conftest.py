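import numpy as np
import pytest

from loomsight.synthgen import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240118)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced-scale cohort for simulation-heavy tests."""
    return CohortConfig(
        n_subjects=12,
        grid_shape=(12, 12, 12),
        effect_center=(6, 6, 6),
        pupil_sampling_rate=250.0,
        n_pupil_trials=8,
    )
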