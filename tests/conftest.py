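import numpy as np
import pytest

from aimgen.preprocess import cohort_series
from aimgen.simulate import CohortConfig, simulate_cohort

#: frozen implicit field with deterministic aiming: no noise, no learning
#: (preset amplitude), kernel center glued to the current aim.  Used wherever
#: an exact kernel-evaluation oracle is asserted.
FROZEN_AMPLITUDE = 18.0
FROZEN_WIDTH = 35.0


def frozen_noiseless_config(**overrides) -> CohortConfig:
    kwargs = dict(
        motor_noise_sd=0.0,
        retention_a=1.0,
        p_reaim=1.0,
        center_rate=1.0,
        initial_amplitude=FROZEN_AMPLITUDE,
        learning_rate_b_mean=0.0,
        learning_rate_b_sd=0.0,
        learning_rate_b_min=0.0,
        kernel_width_mean=FROZEN_WIDTH,
        kernel_width_sd=0.0,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def gaussian_kernel(delta, width: float = FROZEN_WIDTH):
    return np.exp(-(np.asarray(delta, dtype=float) ** 2) / (2.0 * width**2))


@pytest.fixture(scope="session")
def cohort_trials():
    """One default-config cohort (70 subjects, 7 groups), fixed seed."""
    return simulate_cohort(seed=7)


@pytest.fixture(scope="session")
def cohort_by_subject(cohort_trials):
    return cohort_series(cohort_trials)


@pytest.fixture(scope="session")
def noiseless_trials():
    return simulate_cohort(frozen_noiseless_config(), seed=11)
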