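import numpy as np
import pytest

from cmjump import JumpSpec, run_study, simulate_jump

# fixed seeds for the reproducible study conditions used across the suite
STUDY_SEED = 11
STUDY_N = 200


@pytest.fixture(scope="session")
def clean_pair():
    """Noise-free, undistorted pair at h_true = 0.30 m (sampling error only)."""
    return simulate_jump(JumpSpec(h_true=0.30, noise_sd=0.0, wobble=(), sp_gain=1.0))


@pytest.fixture(scope="session")
def noisy_pair():
    """Default corrupted jump at h_true = 0.25 m (gain, wobble, noise on)."""
    return simulate_jump(JumpSpec(h_true=0.25, seed=3))


@pytest.fixture(scope="session")
def study():
    """The full end-to-end study: 200 synthetic jumps, full grid, 5-fold CV.

    Session-scoped because the exhaustive 192-combination grid search is the
    dominant cost of the suite; every consumer reads, never mutates.
    """
    return run_study(n=STUDY_N, seed=STUDY_SEED)
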