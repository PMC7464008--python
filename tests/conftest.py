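import math

import numpy as np
import pytest

from ewalearn import CohortSpec, TaskConfig, simulate_cohort
from ewalearn.ewa import ATTRACTION_FLOOR, SessionData, TrialRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """An 8-participant cohort shared by I/O and statistics tests."""
    spec = CohortSpec(n_participants=8, seed=0)
    return simulate_cohort(spec)


def brute_loglik(trials, alpha, rho, beta, window="all", task=None):
    """Independent straight-line trace of the EWA recursion.

    Deliberately written without arrays or shared code: a plain loop over
    trials updating scalars, used as the oracle for the vectorised
    likelihood implementation.
    """
    task = task or TaskConfig()
    if window == "reversal":
        trials = [t for t in trials if t.trial >= task.reversal_trial]
    A = [0.0, 0.0]
    N = 1.0
    ll = 0.0
    for t in trials:
        w = [max(a, ATTRACTION_FLOOR) ** beta for a in A]
        p = w[t.chosen] / (w[0] + w[1])
        if window != "reversal_carryover" or t.trial >= task.reversal_trial:
            ll += math.log(p)
        n_new = rho * N + 1.0
        for j in (0, 1):
            i_j = 1.0 if (j == t.chosen and t.feedback == 1) else 0.0
            A[j] = ((1.0 - alpha) * N * A[j] + i_j) / n_new
        N = n_new
    return ll


def random_session(rng, n_trials=40, task=None):
    """A session of random choices/feedback (not model-generated)."""
    task = task or TaskConfig(n_trials=n_trials, reversal_trial=n_trials // 2 + 1)
    trials = [
        TrialRecord(
            t,
            int(rng.integers(2)),
            int(rng.integers(2)),
            task.phase_of(t),
        )
        for t in range(1, n_trials + 1)
    ]
    return SessionData("rand", trials, task)
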