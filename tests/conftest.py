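import itertools

import numpy as np
import pytest

from reedcmr import McmcSettings, run_mcmc
from reedcmr.synthetic_data import SimulationScenario, simulate_histories


def enumerate_history_prob(history, first, phi_t, p_t, psi):
    """Brute-force marginal probability of a history by summing over every
    latent state path.  Independent oracle for the forward recursion."""
    history = np.asarray(history)
    T = len(history)
    n_free = T - 1 - first
    total = 0.0
    # after first capture a bird is Resident (1) or Dead (2); Initial (0)
    # is never re-entered
    for combo in itertools.product((1, 2), repeat=n_free):
        states = (0,) + combo
        prob = 1.0
        for k in range(1, len(states)):
            t = first + k
            prev, cur = states[k - 1], states[k]
            phi = phi_t[t - 1]
            if prev == 0:
                prob *= phi * psi if cur == 1 else 1.0 - phi * psi
            elif prev == 1:
                prob *= phi if cur == 1 else 1.0 - phi
            else:
                prob *= 1.0 if cur == 2 else 0.0
            p = p_t[t]
            if cur == 1:
                prob *= p if history[t] else 1.0 - p
            else:
                prob *= 0.0 if history[t] else 1.0
        total += prob
    return total


@pytest.fixture(scope="session")
def small_histories():
    """3 sites x 6 occasions, 300 birds, default-truth regime."""
    scenario = SimulationScenario(
        n_sites=3, n_occasions=6, n_new_per_site_occasion=20, seed=5
    )
    hist, truth = simulate_histories(scenario)
    return hist, truth


@pytest.fixture(scope="session")
def small_fit(small_histories):
    """A short but converged fit of the small synthetic dataset, shared by
    the posterior-summary and derived-output tests."""
    hist, truth = small_histories
    draws = run_mcmc(
        hist,
        McmcSettings(chains=3, iterations=8000, burn_in=4000, thinning=4, seed=9),
    )
    return hist, truth, draws
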