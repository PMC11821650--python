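"""Outcome valuation, Q updates, choice rule, likelihood, and simulation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rplt.behavior import percent_optimal
from rplt.model import (
    AgentParams,
    choice_probabilities,
    negative_log_likelihood,
    outcome_value,
    q_update,
    simulate_agent,
)

unit = st.floats(min_value=0.0, max_value=1.0)
signed_unit = st.floats(min_value=-1.0, max_value=1.0)
beta_open = st.floats(min_value=1e-3, max_value=1 - 1e-3)


def reference_nll(trials: pd.DataFrame, params: AgentParams) -> float:
    """Naive per-trial oracle: explicit softmax, dict-based Q table."""
    from scipy.special import softmax

    tau = min(max(params.beta / (1 - params.beta), 1e-3), 1e3)
    q = {(s, a): 0.0 for s in ("S1", "S2", "S3", "S4") for a in ("A", "B")}
    total = 0.0
    for _, row in trials.sort_values("trial_index").iterrows():
        s = row["stimulus_id"]
        probs = softmax(np.array([q[(s, "A")], q[(s, "B")]]) / tau)
        p = probs[0 if row["response"] == "A" else 1]
        p = min(max(p, 1e-6), 1 - 1e-6)
        total -= math.log(p)
        r = {"reward": 1.0, "punish": -1.0, "none": params.r0}[row["feedback"]]
        key = (s, row["response"])
        pe = r - q[key]
        lr = params.lr_plus if pe > 0 else params.lr_minus
        if pe != 0:
            q[key] += lr * pe
    return total


class TestOutcomeValue:
    @pytest.mark.parametrize(
        "feedback,r0,expected",
        [("reward", 0.3, 1.0), ("punish", 0.3, -1.0), ("none", -0.24, -0.24),
         ("none", 0.0, 0.0)],
    )
    def test_mapping(self, feedback, r0, expected):
        assert outcome_value(feedback, r0) == expected

    def test_unknown_feedback_rejected(self):
        with pytest.raises(ValueError):
            outcome_value("shrug", 0.0)


class TestQUpdate:
    @pytest.mark.parametrize(
        "q,r,lr_plus,lr_minus,expected",
        [
            (0.0, 1.0, 0.5, 0.9, 0.5),  # positive pe uses lr_plus
            (0.5, 0.5, 0.3, 0.7, 0.5),  # pe = 0: no change
            (0.8, -1.0, 0.1, 0.25, 0.35),  # pe = -1.8, 0.8 - 0.25*1.8
        ],
    )
    def test_hand_arithmetic(self, q, r, lr_plus, lr_minus, expected):
        assert q_update(q, r, lr_plus, lr_minus) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None)
    @given(q=signed_unit, r=signed_unit, lrp=unit, lrm=unit)
    def test_update_moves_toward_r_and_stays_bounded(self, q, r, lrp, lrm):
        q2 = q_update(q, r, lrp, lrm)
        assert abs(q2 - r) <= abs(q - r) + 1e-12
        assert -1.0 - 1e-12 <= q2 <= 1.0 + 1e-12


class TestChoiceRule:
    def test_symmetry(self):
        assert choice_probabilities(0.4, 0.4, 0.7) == (0.5, 0.5)

    def test_full_explore_limit(self):
        p_a, p_b = choice_probabilities(1.0, 0.0, 1 - 1e-3)
        assert p_a == pytest.approx(0.5, abs=1e-3)

    def test_unit_temperature_closed_form(self):
        # beta = 0.5 gives tau = 1: plain softmax of the Q difference
        p_a, p_b = choice_probabilities(1.0, 0.0, 0.5)
        assert p_a == pytest.approx(0.7311, abs=1e-4)
        assert p_b == pytest.approx(0.2689, abs=1e-4)

    @settings(max_examples=200, deadline=None)
    @given(q_a=signed_unit, q_b=signed_unit, beta=beta_open)
    def test_probabilities_conserve_and_stay_interior(self, q_a, q_b, beta):
        p_a, p_b = choice_probabilities(q_a, q_b, beta)
        assert p_a + p_b == pytest.approx(1.0)
        assert 0.0 < p_a < 1.0 and 0.0 < p_b < 1.0


class TestLikelihood:
    def test_zero_learning_rate_closed_form(self, learner_session):
        """With both learning rates 0 the Qs never move: negLLE = T ln 2."""
        flat = AgentParams(0.0, 0.0, 0.37, 0.2)
        nll = negative_log_likelihood(learner_session, flat)
        assert nll == pytest.approx(80 * math.log(2), abs=1e-9)

    def test_single_trial_is_ln2(self, learner_session):
        one = learner_session.head(1)
        nll = negative_log_likelihood(one, AgentParams(0.9, 0.1, 0.6, -0.7))
        assert nll == pytest.approx(math.log(2), abs=1e-12)

    def test_matches_naive_reference_loop(self, schedule):
        rng = np.random.default_rng(5)
        for _ in range(10):
            params = AgentParams(
                rng.random(), rng.random(), 1e-3 + 0.998 * rng.random(),
                -1 + 2 * rng.random(),
            )
            trials = simulate_agent(schedule, params, seed=int(rng.integers(2**31)))
            probe = AgentParams(
                rng.random(), rng.random(), 1e-3 + 0.998 * rng.random(),
                -1 + 2 * rng.random(),
            )
            assert negative_log_likelihood(trials, probe) == pytest.approx(
                reference_nll(trials, probe), abs=1e-10
            )

    def test_likelihood_bounds(self, learner_session):
        params = AgentParams(0.8, 0.8, 0.05, -0.9)
        nll = negative_log_likelihood(learner_session, params)
        assert 0.0 <= nll <= 80 * math.log(1e6)

    def test_empty_trials_rejected(self, learner_session):
        with pytest.raises(ValueError):
            negative_log_likelihood(learner_session.iloc[0:0], AgentParams(0, 0, 0.5, 0))

    def test_param_bounds_enforced(self):
        with pytest.raises(ValueError):
            AgentParams(1.2, 0.0, 0.5, 0.0)
        with pytest.raises(ValueError):
            AgentParams(0.5, 0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            AgentParams(0.5, 0.0, 0.5, -1.5)


class TestR0Substitution:
    """R0 at the extremes makes no-feedback identical to explicit outcomes."""

    def _q_trajectory(self, feedbacks, params):
        q = 0.0
        traj = []
        for fb in feedbacks:
            r = outcome_value(fb, params.r0)
            q = q_update(q, r, params.lr_plus, params.lr_minus)
            traj.append(q)
        return traj

    def test_r0_plus_one_equals_reward(self):
        p = AgentParams(0.6, 0.3, 0.5, 1.0)
        assert self._q_trajectory(["none", "none", "punish"], p) == (
            self._q_trajectory(["reward", "reward", "punish"], p)
        )

    def test_r0_minus_one_equals_punishment(self):
        p = AgentParams(0.6, 0.3, 0.5, -1.0)
        assert self._q_trajectory(["none", "reward", "none"], p) == (
            self._q_trajectory(["punish", "reward", "punish"], p)
        )


class TestSimulation:
    def test_fixed_seed_reproducible(self, schedule):
        p = AgentParams(0.4, 0.2, 0.3, 0.1)
        a = simulate_agent(schedule, p, seed=7)
        b = simulate_agent(schedule, p, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_full_explore_agent_is_unbiased(self, schedule):
        p = AgentParams(0.5, 0.5, 1 - 1e-3, 0.0)
        rng = np.random.default_rng(0)
        frac_a = []
        for _ in range(60):
            df = simulate_agent(schedule, p, seed=int(rng.integers(2**31)))
            frac_a.append((df["response"] == "A").mean())
        assert np.mean(frac_a) == pytest.approx(0.5, abs=0.02)

    def test_learner_beats_chance_on_reward_trials(self, schedule):
        p = AgentParams(0.9, 0.9, 0.1, 0.0)
        rng = np.random.default_rng(1)
        vals = [
            percent_optimal(
                simulate_agent(schedule, p, seed=int(rng.integers(2**31))), "reward"
            )
            for _ in range(100)
        ]
        assert np.mean(vals) > 55.0

    def test_increasing_lr_plus_does_not_hurt_reward_learning(self, schedule):
        """Monotonicity in the learning rate, up to sampling noise."""
        means = []
        for lr_plus in (0.0, 0.25, 0.5):
            p = AgentParams(lr_plus, 0.0, 0.3, 0.0)
            rng = np.random.default_rng(3)
            vals = [
                percent_optimal(
                    simulate_agent(schedule, p, seed=int(rng.integers(2**31))),
                    "reward",
                )
                for _ in range(150)
            ]
            means.append(np.mean(vals))
        assert means[1] >= means[0] - 1.5
        assert means[2] >= means[1] - 1.5
        assert means[2] > means[0]

    def test_practice_prefix_flagged(self, schedule):
        df = simulate_agent(
            schedule, AgentParams(0.3, 0.3, 0.4, 0.0), seed=2, include_practice=True
        )
        assert len(df) == 84
        assert df["practice_flag"].sum() == 4
        assert set(df.loc[df["practice_flag"], "stimulus_id"]) == {"P1", "P2"}
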