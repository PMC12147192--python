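import numpy as np
import pytest

from comtransfer.pipeline import analyze_trial
from comtransfer.synthetic_data import SyntheticConfig, simulate_trial


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free 30-step trial with the default work targets."""
    cfg = SyntheticConfig(seed=11, noise_pos_sd=0.0, noise_grf_sd=0.0)
    trial, truth = simulate_trial(cfg)
    return trial, truth


@pytest.fixture(scope="session")
def clean_analyzed(clean_trial):
    trial, truth = clean_trial
    steps, metrics = analyze_trial(trial)
    return trial, truth, steps, metrics


@pytest.fixture(scope="session")
def noisy_trial():
    """Default study-condition trial (1 mm kinematic / 1 N kinetic noise)."""
    cfg = SyntheticConfig(seed=12)
    trial, truth = simulate_trial(cfg)
    return trial, truth


@pytest.fixture(scope="session")
def noisy_analyzed(noisy_trial):
    trial, truth = noisy_trial
    steps, metrics = analyze_trial(trial)
    return trial, truth, steps, metrics


def match_truth(truth_frame, step):
    """Ground-truth row whose IC time matches a detected step."""
    i = (truth_frame.t_ic - step.t_ic).abs().idxmin()
    return truth_frame.loc[i]


def rk4_passive_min_distance(x0, v0, omega, t_end=0.7, dt=1e-5):
    """Independent ODE oracle: minimum |x| of x'' = omega^2 x by RK4.

    Vectorized over initial states; returns the (signed, negative) minimum
    pivot distance reached before the trajectory recedes.
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    v = np.atleast_1d(np.asarray(v0, dtype=float)).copy()
    om2 = np.atleast_1d(np.asarray(omega, dtype=float)) ** 2
    best = np.abs(x)
    n = int(round(t_end / dt))
    for _ in range(n):
        k1x, k1v = v, om2 * x
        k2x, k2v = v + 0.5 * dt * k1v, om2 * (x + 0.5 * dt * k1x)
        k3x, k3v = v + 0.5 * dt * k2v, om2 * (x + 0.5 * dt * k2x)
        k4x, k4v = v + dt * k3v, om2 * (x + dt * k3x)
        x = x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        v = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        np.minimum(best, np.abs(x), out=best)
    return -best
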