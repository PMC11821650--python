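"""Cleaning rules and behavioral summaries (percent optimal, win-stay/lose-shift)."""

import numpy as np
import pandas as pd
import pytest

from rplt.behavior import (
    RetentionError,
    clean_session,
    percent_optimal,
    summarize_session,
    win_stay_lose_shift,
)
from rplt.model import AgentParams, simulate_agent
from tests.conftest import make_trial_row


def brute_force_wsls(trials: pd.DataFrame, valence: str):
    """Exhaustive enumeration over all same-stimulus successive pairs."""
    sub = trials[trials["valence"] == valence].sort_values("trial_index")
    sub = sub.reset_index(drop=True)
    wins = losses = stays = shifts = 0
    for i in range(len(sub)):
        priors = [
            j for j in range(i) if sub.loc[j, "stimulus_id"] == sub.loc[i, "stimulus_id"]
        ]
        if not priors:
            continue
        j = priors[-1]
        fb = sub.loc[j, "feedback"]
        success = fb == "reward" if valence == "reward" else fb == "none"
        same = sub.loc[i, "response"] == sub.loc[j, "response"]
        if success:
            wins += 1
            stays += same
        else:
            losses += 1
            shifts += not same
    ws = 100 * stays / wins if wins else float("nan")
    ls = 100 * shifts / losses if losses else float("nan")
    return ws, ls


class TestCleaning:
    def test_clean_full_session_no_flags(self, learner_session):
        cleaned, flags = clean_session(learner_session)
        assert len(cleaned) == 80
        assert not flags.noncompliant and not flags.partial
        assert flags.excluded_anticipatory_count == 0

    def test_practice_trials_removed(self, schedule):
        df = simulate_agent(
            schedule, AgentParams(0.3, 0.3, 0.4, 0.0), seed=5, include_practice=True
        )
        cleaned, _ = clean_session(df)
        assert not cleaned["practice_flag"].any()
        assert len(cleaned) == 80

    def test_single_key_session_flagged_noncompliant(self, learner_session):
        df = learner_session.copy()
        df["response"] = "A"
        cleaned, flags = clean_session(df)
        assert flags.noncompliant
        assert flags.single_key_warning

    def test_anticipatory_trials_excluded_and_counted(self, learner_session):
        df = learner_session.copy()
        df.loc[df.index[:5], "rt_ms"] = 150.0
        cleaned, flags = clean_session(df)
        assert len(cleaned) == 75
        assert flags.excluded_anticipatory_count == 5
        assert flags.partial

    def test_partial_session_retained(self, learner_session):
        df = learner_session.head(55)
        cleaned, flags = clean_session(df)
        assert len(cleaned) == 55
        assert flags.partial and not flags.noncompliant

    def test_short_session_rejected(self, learner_session):
        with pytest.raises(RetentionError):
            clean_session(learner_session.head(49))

    def test_cleaning_preserves_retained_rows(self, learner_session):
        df = learner_session.copy()
        df.loc[df.index[10], "rt_ms"] = 100.0
        cleaned, _ = clean_session(df)
        expected = df[df["rt_ms"] >= 200.0]
        pd.testing.assert_frame_equal(
            cleaned.reset_index(drop=True), expected.reset_index(drop=True)
        )


class TestPercentOptimal:
    def test_optimal_is_frequent_category_not_outcome(self):
        """Response = frequent category counts as optimal even when incorrect."""
        rows = []
        # S1 (frequent A): 6 optimal responses, 2 of them on infrequent
        # (assigned B) trials, plus 4 non-optimal responses.
        for i in range(1, 5):
            rows.append(make_trial_row(i, "S1", "A", "reward", assigned_category="A"))
        for i in range(5, 7):
            rows.append(make_trial_row(i, "S1", "A", "none", assigned_category="B"))
        for i in range(7, 11):
            rows.append(make_trial_row(i, "S1", "B", "none", assigned_category="A"))
        df = pd.DataFrame(rows)
        assert percent_optimal(df, "reward") == pytest.approx(60.0)

    def test_all_optimal(self, schedule):
        rows = [
            make_trial_row(
                t.trial_index,
                t.stimulus_id,
                t.frequent_category,
                "none",
                assigned_category=t.assigned_category,
            )
            for t in schedule.trials
        ]
        df = pd.DataFrame(rows)
        assert percent_optimal(df, "reward") == 100.0
        assert percent_optimal(df, "punishment") == 100.0

    def test_zero_denominator_is_nan(self):
        df = pd.DataFrame([make_trial_row(1, "S1", "A", "reward")])
        assert np.isnan(percent_optimal(df, "punishment"))

    def test_invariant_to_trial_order(self, learner_session):
        shuffled = learner_session.sample(frac=1.0, random_state=3)
        assert percent_optimal(shuffled, "reward") == pytest.approx(
            percent_optimal(learner_session, "reward")
        )


class TestWinStayLoseShift:
    def test_one_of_each_transition(self):
        rows = [
            make_trial_row(1, "S1", "A", "reward"),   # win ...
            make_trial_row(2, "S1", "A", "reward"),   # ... stay
            make_trial_row(3, "S1", "A", "none"),     # lose ...
            make_trial_row(4, "S1", "B", "none"),     # ... shift
        ]
        ws, ls = win_stay_lose_shift(pd.DataFrame(rows), "reward")
        assert ws == 100.0 and ls == 100.0

    def test_punished_repeat_is_not_a_shift(self):
        rows = [
            make_trial_row(1, "S3", "B", "punish", assigned_category="A"),
            make_trial_row(2, "S3", "B", "punish", assigned_category="A"),
        ]
        ws, ls = win_stay_lose_shift(pd.DataFrame(rows), "punishment")
        assert ls == 0.0
        assert np.isnan(ws)

    def test_matches_brute_force_on_constructed_log(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(1, 21):
            stim = rng.choice(["S1", "S2", "S3", "S4"])
            resp = rng.choice(["A", "B"])
            valence = "reward" if stim in ("S1", "S2") else "punishment"
            if valence == "reward":
                fb = rng.choice(["reward", "none"])
            else:
                fb = rng.choice(["punish", "none"])
            rows.append(make_trial_row(i, stim, resp, fb))
        df = pd.DataFrame(rows)
        for valence in ("reward", "punishment"):
            got = win_stay_lose_shift(df, valence)
            want = brute_force_wsls(df, valence)
            assert got == pytest.approx(want, nan_ok=True)

    def test_matches_brute_force_on_simulated_sessions(self, schedule):
        rng = np.random.default_rng(13)
        for _ in range(5):
            p = AgentParams(rng.random(), rng.random(), 0.2 + 0.6 * rng.random(), 0.0)
            df = simulate_agent(schedule, p, seed=int(rng.integers(2**31)))
            for valence in ("reward", "punishment"):
                assert win_stay_lose_shift(df, valence) == pytest.approx(
                    brute_force_wsls(df, valence), nan_ok=True
                )

    def test_depends_on_trial_order(self, schedule):
        """Unlike percent optimal, WSLS is sequential: shuffling changes it."""
        p = AgentParams(0.7, 0.7, 0.15, 0.0)
        df = simulate_agent(schedule, p, seed=99)
        base = win_stay_lose_shift(df, "reward")
        changed = False
        for rs in range(5):
            shuffled = df.sample(frac=1.0, random_state=rs).reset_index(drop=True)
            shuffled["trial_index"] = np.arange(1, len(shuffled) + 1)
            if win_stay_lose_shift(shuffled, "reward") != pytest.approx(base):
                changed = True
                break
        assert changed

    def test_explorer_stays_about_half_the_time(self, schedule):
        p = AgentParams(0.5, 0.5, 1 - 1e-3, 0.0)
        rng = np.random.default_rng(21)
        ws = [
            win_stay_lose_shift(
                simulate_agent(schedule, p, seed=int(rng.integers(2**31))), "reward"
            )[0]
            for _ in range(100)
        ]
        assert np.nanmean(ws) == pytest.approx(50.0, abs=2.5)


class TestSummary:
    def test_summary_fields(self, learner_session):
        cleaned, flags = clean_session(learner_session)
        s = summarize_session(cleaned, flags)
        assert s.session_id == "fixture-learner"
        assert s.n_trials_used == 80
        for v in (
            s.pct_optimal_reward,
            s.pct_optimal_punishment,
            s.win_stay_reward,
            s.lose_shift_reward,
            s.win_stay_punishment,
            s.lose_shift_punishment,
        ):
            assert 0.0 <= v <= 100.0
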