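import numpy as np
import pytest

from liftrisk import FilterSpec, SimConfig
from liftrisk.preprocessing import bandpass_filter, pad_trial
from liftrisk.simulate import simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quick_sim_config():
    """Small but structurally complete dataset: 24 trials, short lifts."""
    return SimConfig(
        n_subjects=1,
        trials_per_zone_per_subject=2,
        duration_range=(4.0, 6.0),
        noise_sd=0.2,
        class_separation=1.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def quick_trials(quick_sim_config):
    return simulate_dataset(quick_sim_config)


@pytest.fixture(scope="session")
def quick_tensors(quick_trials):
    spec = FilterSpec()
    return [pad_trial(bandpass_filter(t, spec)) for t in quick_trials]


def numeric_gradient(f, x, eps=1e-5):
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, dtype=np.float64)
    grad = np.zeros_like(x)
    flat = x.ravel()
    gflat = grad.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f(x)
        flat[i] = orig - eps
        lo = f(x)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return grad
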