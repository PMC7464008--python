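"""Unit and property tests for the EWA learning core."""

import math

import numpy as np
import pytest

from ewalearn import (
    AttractionState,
    EWAParams,
    TaskConfig,
    choice_probabilities,
    session_log_likelihood,
    simulate_agent,
    update_attractions,
    update_experience_weight,
)
from ewalearn.ewa import SessionData, TrialRecord

from conftest import brute_loglik, random_session


@pytest.mark.parametrize(
    "n_prev, rho, expected",
    [
        (1.0, 0.0, 1.0),  # zero memory: weight stays at 1 forever
        (1.0, 1.0, 2.0),
        (2.25, 0.4, 1.9),
    ],
)
def test_experience_weight_update(n_prev, rho, expected):
    assert update_experience_weight(n_prev, rho) == pytest.approx(expected, abs=1e-12)


def test_experience_weight_rejects_bad_rho():
    with pytest.raises(ValueError):
        update_experience_weight(1.0, 1.5)
    with pytest.raises(ValueError):
        update_experience_weight(1.0, -0.1)


class TestAttractionUpdate:
    def test_rescorla_wagner_special_case(self):
        # rho=0 keeps N at 1, so the update is the plain RW delta rule
        state = AttractionState((0.5, 0.2), 1.0)
        new = update_attractions(state, alpha=0.3, rho=0.0, chosen=0, feedback=1)
        assert new.attractions == pytest.approx((1.35, 0.14))
        assert new.experience_weight == 1.0
        assert new.trial_index == 1

    def test_alpha_one_erases_history(self):
        state = AttractionState((0.9, 0.1), 3.0)
        new = update_attractions(state, alpha=1.0, rho=0.5, chosen=1, feedback=1)
        n_new = 0.5 * 3.0 + 1.0
        assert new.attractions[0] == 0.0
        assert new.attractions[1] == pytest.approx(1.0 / n_new)

    def test_no_learning_no_feedback(self):
        state = AttractionState((0.4, 0.8), 3.0)
        new = update_attractions(state, alpha=0.0, rho=1.0, chosen=0, feedback=0)
        assert new.experience_weight == 4.0
        assert new.attractions == pytest.approx((0.3, 0.6))

    def test_rho_zero_reduces_to_rescorla_wagner_exactly(self, rng):
        # property: with rho=0, A(t) = (1-alpha)*A(t-1) + I for any history
        alpha = 0.37
        state = AttractionState((0.0, 0.0), 1.0)
        rw = [0.0, 0.0]
        for _ in range(50):
            chosen = int(rng.integers(2))
            fb = int(rng.integers(2))
            state = update_attractions(state, alpha, 0.0, chosen, fb)
            for j in (0, 1):
                rw[j] = (1 - alpha) * rw[j] + (1.0 if j == chosen and fb else 0.0)
            assert state.experience_weight == 1.0
            assert state.attractions == pytest.approx(tuple(rw), abs=1e-14)

    def test_rho_one_counts_trials(self):
        state = AttractionState((0.0, 0.0), 1.0)
        for t in range(1, 30):
            state = update_attractions(state, 0.5, 1.0, 0, 1)
            assert state.experience_weight == t + 1


class TestChoiceRule:
    @pytest.mark.parametrize(
        "attractions, beta, expected",
        [
            ((1.0, 1.0), 1.5, (0.5, 0.5)),
            ((4.0, 1.0), 1.0, (0.8, 0.2)),
            ((0.0, 0.0), 2.0, (0.5, 0.5)),  # all-floored start is uniform
            ((5.0, 1.0), 0.0, (0.5, 0.5)),  # beta=0 means pure randomness
        ],
    )
    def test_examples(self, attractions, beta, expected):
        probs = choice_probabilities(AttractionState(attractions), beta)
        assert probs == pytest.approx(expected, abs=1e-12)

    def test_negative_attraction_rejected(self):
        with pytest.raises(ValueError):
            AttractionState((-0.1, 0.5))

    def test_normalisation_property(self, rng):
        for _ in range(1000):
            a = tuple(rng.uniform(0, 5, size=2))
            beta = rng.uniform(0, 8)
            probs = choice_probabilities(AttractionState(a), beta)
            assert abs(probs.sum() - 1.0) < 1e-12
            assert np.all(probs > 0) and np.all(probs < 1)

    def test_greed_monotone_in_beta(self, rng):
        # with A0 > A1, raising beta never lowers P(choice 0)
        for _ in range(100):
            a1 = rng.uniform(0, 2)
            a0 = a1 + rng.uniform(0.01, 2)
            betas = np.sort(rng.uniform(0, 6, size=5))
            p0 = [
                choice_probabilities(AttractionState((a0, a1)), b)[0] for b in betas
            ]
            assert np.all(np.diff(p0) >= -1e-12)


class TestSessionLikelihood:
    def test_first_trial_is_uniform(self):
        task = TaskConfig(n_trials=2, reversal_trial=2)
        session = SessionData("p", [TrialRecord(1, 0, 1)], task)
        ll = session_log_likelihood(session, EWAParams(0.9, 0.9, 3.0))
        assert ll == pytest.approx(math.log(0.5), abs=1e-12)

    def test_three_trial_hand_trace(self):
        task = TaskConfig(n_trials=3, reversal_trial=3)
        trials = [TrialRecord(1, 0, 1), TrialRecord(2, 0, 0), TrialRecord(3, 1, 1)]
        session = SessionData("p", trials, task)
        params = EWAParams(0.5, 0.5, 1.0)
        expected = brute_loglik(trials, 0.5, 0.5, 1.0)
        assert session_log_likelihood(session, params) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize("window", ["all", "reversal", "reversal_carryover"])
    def test_matches_brute_force_oracle(self, rng, window):
        for _ in range(30):
            session = random_session(rng, n_trials=40)
            alpha, rho = rng.uniform(0, 1, size=2)
            beta = rng.uniform(0, 6)
            got = session_log_likelihood(
                session, EWAParams(alpha, rho, beta), window
            )
            want = brute_loglik(
                session.trials, alpha, rho, beta, window, session.task
            )
            assert got == pytest.approx(want, abs=1e-10)

    def test_strictly_negative(self, rng):
        session = random_session(rng)
        ll = session_log_likelihood(session, EWAParams(0.5, 0.5, 1.0))
        assert ll < 0

    def test_empty_window_raises(self):
        task = TaskConfig(n_trials=4, reversal_trial=3)
        trials = [TrialRecord(1, 0, 1), TrialRecord(2, 1, 0)]
        session = SessionData("p", trials, task)
        with pytest.raises(ValueError):
            session_log_likelihood(session, EWAParams(0.5, 0.5, 1.0), "reversal")


class TestAgentSimulation:
    def test_deterministic_under_seed(self):
        params = EWAParams(0.6, 0.3, 1.5)
        s1 = simulate_agent(params, seed=7)
        s2 = simulate_agent(params, seed=7)
        assert s1.trials == s2.trials

    def test_high_beta_is_greedy(self):
        task = TaskConfig(n_trials=1000, reversal_trial=1000)
        session = simulate_agent(EWAParams(0.6, 0.3, 50.0), task, seed=3)
        pre = [t.chosen for t in session.trials[50:999]]
        freq = max(np.mean(pre), 1 - np.mean(pre))
        assert freq > 0.95

    def test_beta_zero_is_uniform(self):
        task = TaskConfig(n_trials=10_000, reversal_trial=5001)
        session = simulate_agent(EWAParams(0.5, 0.5, 0.0), task, seed=11)
        freq = np.mean([t.chosen for t in session.trials])
        assert abs(freq - 0.5) < 0.02

    def test_trial_metadata(self):
        session = simulate_agent(EWAParams(0.5, 0.5, 1.0), seed=1)
        assert len(session.trials) == 80
        assert [t.trial for t in session.trials] == list(range(1, 81))
        assert {t.phase for t in session.trials[:40]} == {"discrimination"}
        assert {t.phase for t in session.trials[40:]} == {"reversal"}


def test_param_validation():
    with pytest.raises(ValueError):
        EWAParams(-0.1, 0.5, 1.0)
    with pytest.raises(ValueError):
        EWAParams(0.5, 1.2, 1.0)
    with pytest.raises(ValueError):
        EWAParams(0.5, 0.5, -1.0)
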