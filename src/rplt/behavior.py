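"""Session cleaning and behavioral summaries.

Cleaning rules follow the live task's conventions: practice trials are never
scored; responses faster than 200 ms are anticipatory and excluded; a session
in which a single response key accounts for every response is flagged
noncompliant; sessions interrupted after 50-63 trials are retained and scored
as partial, while sessions with fewer than 50 usable trials are rejected.

Summaries are per valence.  "Percent optimal" is the percent of trials on
which the response matched the stimulus's *frequent* category -- the optimal
choice -- regardless of whether it happened to be correct on that trial.
Win-stay / lose-shift condition on the most recent prior trial of the *same
stimulus*, with success defined per valence: explicit reward for
reward-valenced stimuli, avoided punishment (no feedback) for
punishment-valenced ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .task import STIMULI

__all__ = [
    "RetentionError",
    "CleanFlags",
    "SessionSummary",
    "clean_session",
    "percent_optimal",
    "win_stay_lose_shift",
    "summarize_session",
    "ANTICIPATORY_RT_MS",
    "MIN_TRIALS",
    "FULL_TRIALS",
]

ANTICIPATORY_RT_MS = 200.0
MIN_TRIALS = 50
FULL_TRIALS = 80
SINGLE_KEY_WARN_FRACTION = 0.975


class RetentionError(ValueError):
    """Session has too few usable trials to be scored or fit."""


@dataclass(frozen=True)
class CleanFlags:
    noncompliant: bool
    partial: bool
    excluded_anticipatory_count: int
    single_key_warning: bool = False


@dataclass(frozen=True)
class SessionSummary:
    """Behavioral block of the per-session summary table.

    Percents are in [0, 100]; a metric with an empty denominator is NaN.
    """

    session_id: str
    pct_optimal_reward: float
    pct_optimal_punishment: float
    win_stay_reward: float
    lose_shift_reward: float
    win_stay_punishment: float
    lose_shift_punishment: float
    n_trials_used: int
    flags: CleanFlags = field(
        default_factory=lambda: CleanFlags(False, False, 0, False)
    )


def clean_session(raw: pd.DataFrame) -> tuple[pd.DataFrame, CleanFlags]:
    """Apply the cleaning rules to a raw trial log.

    Returns the retained (scorable) trials, contents untouched, plus flags.
    Raises :class:`RetentionError` if fewer than 50 usable trials remain.
    """
    task = raw[~raw["practice_flag"].astype(bool)]
    if len(task) == 0:
        raise RetentionError("no non-practice trials in log")
    responses = task["response"]
    single_key_frac = responses.value_counts(normalize=True).max()
    noncompliant = bool(single_key_frac >= 1.0 and responses.nunique() == 1)
    warn = bool(single_key_frac >= SINGLE_KEY_WARN_FRACTION)
    anticipatory = task["rt_ms"] < ANTICIPATORY_RT_MS
    retained = task[~anticipatory]
    n = len(retained)
    if n < MIN_TRIALS:
        raise RetentionError(
            f"only {n} usable trials after cleaning; at least {MIN_TRIALS} required"
        )
    flags = CleanFlags(
        noncompliant=noncompliant,
        partial=bool(MIN_TRIALS <= n < FULL_TRIALS),
        excluded_anticipatory_count=int(anticipatory.sum()),
        single_key_warning=warn,
    )
    return retained, flags


def _valence_trials(trials: pd.DataFrame, valence: str) -> pd.DataFrame:
    if valence not in ("reward", "punishment"):
        raise ValueError(f"valence must be 'reward' or 'punishment', got {valence!r}")
    return trials[trials["valence"] == valence]


def percent_optimal(trials: pd.DataFrame, valence: str) -> float:
    """Percent of trials of a valence on which the response was optimal.

    Optimal means matching the stimulus's frequent category; the category
    assigned on the specific trial is irrelevant.  NaN if no such trials.
    """
    sub = _valence_trials(trials, valence)
    if len(sub) == 0:
        return float("nan")
    frequent = sub["stimulus_id"].map(
        {sid: spec.frequent_category for sid, spec in STIMULI.items()}
    )
    return 100.0 * float((sub["response"].to_numpy() == frequent.to_numpy()).mean())


def win_stay_lose_shift(trials: pd.DataFrame, valence: str) -> tuple[float, float]:
    """Win-stay and lose-shift percentages for one valence.

    For each trial, the reference is the most recent prior trial of the same
    stimulus.  A prior reward-stimulus trial is a success iff explicit reward
    was delivered; a prior punishment-stimulus trial is a success iff
    punishment was avoided (no feedback).  Win-stay is the percent of
    successful-prior pairs where the response repeated; lose-shift the percent
    of failed-prior pairs where it switched.  NaN where the denominator is
    empty.
    """
    sub = _valence_trials(trials, valence).sort_values("trial_index")
    stays_after_win = wins = shifts_after_loss = losses = 0
    last_by_stim: dict[str, tuple[str, str]] = {}  # stimulus -> (response, feedback)
    for stim, response, feedback in zip(
        sub["stimulus_id"], sub["response"], sub["feedback"]
    ):
        prior = last_by_stim.get(stim)
        if prior is not None:
            prior_response, prior_feedback = prior
            success = (
                prior_feedback == "reward" if valence == "reward"
                else prior_feedback == "none"
            )
            if success:
                wins += 1
                stays_after_win += response == prior_response
            else:
                losses += 1
                shifts_after_loss += response != prior_response
        last_by_stim[stim] = (response, feedback)
    win_stay = 100.0 * stays_after_win / wins if wins else float("nan")
    lose_shift = 100.0 * shifts_after_loss / losses if losses else float("nan")
    return win_stay, lose_shift


def summarize_session(
    trials: pd.DataFrame, flags: CleanFlags | None = None
) -> SessionSummary:
    """Compute the full behavioral summary for one cleaned session."""
    ws_r, ls_r = win_stay_lose_shift(trials, "reward")
    ws_p, ls_p = win_stay_lose_shift(trials, "punishment")
    session_id = str(trials["session_id"].iloc[0]) if len(trials) else ""
    return SessionSummary(
        session_id=session_id,
        pct_optimal_reward=percent_optimal(trials, "reward"),
        pct_optimal_punishment=percent_optimal(trials, "punishment"),
        win_stay_reward=ws_r,
        lose_shift_reward=ls_r,
        win_stay_punishment=ws_p,
        lose_shift_punishment=ls_p,
        n_trials_used=int(len(trials)),
        flags=flags or CleanFlags(False, False, 0, False),
    )


def summaries_frame(summaries: list[SessionSummary]) -> pd.DataFrame:
    """Stack SessionSummary records into the session-summary table."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "session_id": s.session_id,
                "pct_optimal_reward": s.pct_optimal_reward,
                "pct_optimal_punishment": s.pct_optimal_punishment,
                "win_stay_reward": s.win_stay_reward,
                "lose_shift_reward": s.lose_shift_reward,
                "win_stay_punishment": s.win_stay_punishment,
                "lose_shift_punishment": s.lose_shift_punishment,
                "n_trials_used": s.n_trials_used,
                "noncompliant": s.flags.noncompliant,
                "partial": s.flags.partial,
                "excluded_anticipatory_count": s.flags.excluded_anticipatory_count,
            }
        )
    return pd.DataFrame(rows)
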