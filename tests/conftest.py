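import numpy as np
import pytest

from pupilwm.synth import (PupilEffectSpec, SimConfig,
                           generate_category_structure,
                           simulate_delayed_estimation, simulate_pupil)


@pytest.fixture(scope="session")
def structure7():
    """Noise-free 7-category structure with equally spaced boundaries."""
    return generate_category_structure(7, jitter=0.0, seed=0)


@pytest.fixture(scope="session")
def small_trials(structure7):
    """Small delayed-estimation table: 6 participants, 12 trials/cell."""
    cfg = SimConfig(n_participants=6, trials_per_cell=12, seed=11)
    return simulate_delayed_estimation(structure7, cfg, seed=11)


def fast_pupil_spec(**overrides) -> PupilEffectSpec:
    """100-Hz pupil spec for quick tests; effect defaults unchanged."""
    params = dict(sample_rate_hz=100.0, blink_rate=0.5)
    params.update(overrides)
    return PupilEffectSpec(**params)


def null_pupil_spec(**overrides) -> PupilEffectSpec:
    """100-Hz spec with every systematic effect switched off."""
    params = dict(load_slope=0.0,
                  interaction_amplitude_by_load={1: 0.0, 2: 0.0,
                                                 3: 0.0, 4: 0.0})
    params.update(overrides)
    return fast_pupil_spec(**params)


@pytest.fixture(scope="session")
def small_traces(structure7, small_trials):
    spec = fast_pupil_spec()
    return simulate_pupil(small_trials, spec, seed=42), spec


def rng_errors(kappa, guess, n, seed):
    """Draw signed errors from the von Mises + uniform mixture."""
    rng = np.random.default_rng(seed)
    guesses = rng.random(n) < guess
    vm = np.rad2deg(rng.vonmises(0.0, kappa, n)) if kappa > 0 else \
        rng.uniform(-180.0, 180.0, n)
    unif = rng.uniform(-180.0, 180.0, n)
    return np.where(guesses, unif, vm)
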