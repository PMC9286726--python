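"""Shared fixtures: well-separated synthetic states and cohort helpers."""

import numpy as np
import pytest

from dynfc.dynamic_connectivity import WindowSpec, sliding_window_correlations
from dynfc.synthetic_data import CohortSpec, make_state_covariance, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_states():
    """Two latent states with strongly contrasting connectivity."""
    return (
        make_state_covariance(0.6, -0.5, 0.0, state_id=0),
        make_state_covariance(-0.5, 0.6, 0.0, state_id=1),
    )


@pytest.fixture(scope="session")
def three_states(two_states):
    return (*two_states, make_state_covariance(0.1, 0.1, 0.6, state_id=2))


@pytest.fixture(scope="session")
def window_spec():
    return WindowSpec(length=20)


def build_cohort(states, *, name="g", n_subjects=10, T=300, p_self=0.9, seed=0,
                 noise=0.0, tr=2.3):
    return CohortSpec(
        group_name=name,
        n_subjects=n_subjects,
        states=tuple(states),
        self_transition=p_self,
        n_timepoints=T,
        tr=tr,
        emission_noise_sd=noise,
        seed=seed,
    )


def cohort_windows(cohort, spec):
    """Simulate a cohort and return (series, true_labels, per-subject z6)."""
    series, labels = simulate_cohort(cohort)
    z6 = [sliding_window_correlations(ts, spec).z6 for ts in series]
    return series, labels, z6


def blurred_truth(states, spec, n_states):
    """Oracle: taper-weighted majority state per window (windowing-blurred)."""
    from dynfc.dynamic_connectivity import exponential_weights

    w = exponential_weights(spec)
    T, L = len(states), spec.length
    out = []
    for start in range(0, T - L + 1, spec.step):
        mass = np.bincount(states[start : start + L], weights=w, minlength=n_states)
        out.append(int(np.argmax(mass)))
    return np.array(out)
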