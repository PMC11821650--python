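"""Probabilistic category-learning task: trial schedule and feedback rules.

The task presents four abstract stimuli (S1--S4), each of which must be
classified into category A or B.  S1 and S2 are reward-valenced: a correct
classification earns +25 points with explicit positive feedback, an incorrect
one yields no feedback.  S3 and S4 are punishment-valenced: an incorrect
classification loses 25 points with explicit negative feedback, a correct one
yields no feedback.  The no-feedback outcome is therefore ambiguous -- it can
mean a missed reward or an avoided punishment.

Category mappings are probabilistic: S1 and S3 belong to category A on 80% of
their trials, S2 and S4 to category B on 80%.  The task runs 80 trials in two
blocks of 40; each block contains 10 trials per stimulus, 8 paired with the
frequent category and 2 with the infrequent one, in a pseudorandom order that
is fixed across participants, with the constraint that each stimulus's first
appearance is paired with its frequent category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "STIMULI",
    "StimulusSpec",
    "ScheduledTrial",
    "TrialSchedule",
    "FeedbackOutcome",
    "build_schedule",
    "canonical_schedule",
    "resolve_feedback",
    "validate_schedule",
    "STARTING_TALLY",
    "CANONICAL_SCHEDULE_SEED",
]

Valence = Literal["reward", "punishment"]
Category = Literal["A", "B"]
Feedback = Literal["reward", "punish", "none"]

#: Points shown on screen at the start of the session.  A UI convention only:
#: the tally plays no role in model fitting and may go negative in simulation.
STARTING_TALLY = 500

#: Seed of the one canonical schedule shipped with the package.  The original
#: task used a single fixed pseudorandom order for all participants; this
#: package regenerates one fixed order satisfying the same constraints.
CANONICAL_SCHEDULE_SEED = 20190301

POINTS_PER_TRIAL = 25
TRIALS_PER_BLOCK = 40
N_BLOCKS = 2
TRIALS_PER_STIM_PER_BLOCK = 10
FREQUENT_PER_STIM_PER_BLOCK = 8


@dataclass(frozen=True)
class StimulusSpec:
    """Static properties of one of the four task stimuli."""

    stimulus_id: str
    valence: Valence
    frequent_category: Category


#: The fixed 2x2 stimulus design: valence crossed with frequent category.
STIMULI: dict[str, StimulusSpec] = {
    "S1": StimulusSpec("S1", "reward", "A"),
    "S2": StimulusSpec("S2", "reward", "B"),
    "S3": StimulusSpec("S3", "punishment", "A"),
    "S4": StimulusSpec("S4", "punishment", "B"),
}


@dataclass(frozen=True)
class ScheduledTrial:
    """One planned trial: which stimulus appears and which category is correct."""

    trial_index: int  # 1-based over the whole task
    block: int  # 1 or 2
    stimulus_id: str
    assigned_category: Category

    @property
    def valence(self) -> Valence:
        return STIMULI[self.stimulus_id].valence

    @property
    def frequent_category(self) -> Category:
        return STIMULI[self.stimulus_id].frequent_category


@dataclass(frozen=True)
class TrialSchedule:
    """An ordered 80-trial schedule (two blocks of 40)."""

    trials: tuple[ScheduledTrial, ...]
    schedule_id: str = "canonical"

    def __len__(self) -> int:
        return len(self.trials)

    def block(self, which: int) -> tuple[ScheduledTrial, ...]:
        return tuple(t for t in self.trials if t.block == which)


@dataclass(frozen=True)
class FeedbackOutcome:
    """Resolved outcome of a response on a scheduled trial."""

    feedback: Feedback
    tally_delta: int
    correct: bool


def _other(category: Category) -> Category:
    return "B" if category == "A" else "A"


def build_schedule(
    schedule_seed: int = CANONICAL_SCHEDULE_SEED, enforce_fixed: bool = True
) -> TrialSchedule:
    """Generate a schedule satisfying all task constraints.

    Each block is a uniform shuffle of the 40-trial multiset (per stimulus:
    8 frequent-category + 2 infrequent-category trials); afterwards, if a
    stimulus's first appearance in the block carries the infrequent category,
    it is swapped with that stimulus's first frequent-category appearance.
    No ordering constraint beyond first-occurrence is imposed.

    Parameters
    ----------
    schedule_seed
        Seed of the shuffle; the same seed always yields the same schedule.
    enforce_fixed
        If True (default), ``schedule_seed`` is ignored and the canonical
        fixed seed is used, mirroring the fixed-across-participants order of
        the live task.
    """
    if schedule_seed < 0:
        raise ValueError("schedule_seed must be >= 0")
    seed = CANONICAL_SCHEDULE_SEED if enforce_fixed else schedule_seed
    rng = np.random.default_rng(seed)
    trials: list[ScheduledTrial] = []
    index = 1
    for block in (1, 2):
        # 40-trial multiset: (stimulus, is_frequent) pairs.
        pool: list[tuple[str, bool]] = []
        for sid in STIMULI:
            pool.extend([(sid, True)] * FREQUENT_PER_STIM_PER_BLOCK)
            pool.extend(
                [(sid, False)]
                * (TRIALS_PER_STIM_PER_BLOCK - FREQUENT_PER_STIM_PER_BLOCK)
            )
        order = rng.permutation(len(pool))
        block_plan = [pool[i] for i in order]
        # First appearance of each stimulus must be frequent-category.
        for sid in STIMULI:
            positions = [i for i, (s, _) in enumerate(block_plan) if s == sid]
            first = positions[0]
            if not block_plan[first][1]:
                swap = next(i for i in positions if block_plan[i][1])
                block_plan[first], block_plan[swap] = (
                    block_plan[swap],
                    block_plan[first],
                )
        for sid, is_frequent in block_plan:
            freq = STIMULI[sid].frequent_category
            trials.append(
                ScheduledTrial(
                    trial_index=index,
                    block=block,
                    stimulus_id=sid,
                    assigned_category=freq if is_frequent else _other(freq),
                )
            )
            index += 1
    label = "canonical" if enforce_fixed else f"seed-{seed}"
    return TrialSchedule(trials=tuple(trials), schedule_id=label)


_CANONICAL: TrialSchedule | None = None


def canonical_schedule() -> TrialSchedule:
    """The single fixed schedule used by default throughout the package."""
    global _CANONICAL
    if _CANONICAL is None:
        _CANONICAL = build_schedule(enforce_fixed=True)
    return _CANONICAL


def resolve_feedback(trial: ScheduledTrial, response: str) -> FeedbackOutcome:
    """Apply the task's asymmetric feedback rule to a response.

    Reward-valenced trials give explicit reward (+25) when the response matches
    the assigned category and nothing otherwise; punishment-valenced trials
    give explicit punishment (-25) when the response mismatches and nothing
    otherwise.
    """
    if response not in ("A", "B"):
        raise ValueError(f"response must be 'A' or 'B', got {response!r}")
    correct = response == trial.assigned_category
    if trial.valence == "reward":
        if correct:
            return FeedbackOutcome("reward", POINTS_PER_TRIAL, True)
        return FeedbackOutcome("none", 0, False)
    if not correct:
        return FeedbackOutcome("punish", -POINTS_PER_TRIAL, False)
    return FeedbackOutcome("none", 0, True)


def validate_schedule(schedule: TrialSchedule) -> list[str]:
    """Check every schedule invariant; return a list of violations (empty if valid)."""
    violations: list[str] = []
    trials = schedule.trials
    n_expected = N_BLOCKS * TRIALS_PER_BLOCK
    if len(trials) != n_expected:
        violations.append(f"length: expected {n_expected} trials, got {len(trials)}")
    for i, t in enumerate(trials, start=1):
        if t.trial_index != i:
            violations.append(
                f"trial_index: expected {i} at position {i}, got {t.trial_index}"
            )
            break
    for block in range(1, N_BLOCKS + 1):
        block_trials = [t for t in trials if t.block == block]
        if len(block_trials) != TRIALS_PER_BLOCK:
            violations.append(
                f"block {block}: expected {TRIALS_PER_BLOCK} trials, "
                f"got {len(block_trials)}"
            )
        for sid, spec in STIMULI.items():
            stim_trials = [t for t in block_trials if t.stimulus_id == sid]
            if len(stim_trials) != TRIALS_PER_STIM_PER_BLOCK:
                violations.append(
                    f"block {block} stimulus {sid}: expected "
                    f"{TRIALS_PER_STIM_PER_BLOCK} trials, got {len(stim_trials)}"
                )
                continue
            n_freq = sum(
                t.assigned_category == spec.frequent_category for t in stim_trials
            )
            if n_freq != FREQUENT_PER_STIM_PER_BLOCK:
                violations.append(
                    f"block {block} stimulus {sid}: expected "
                    f"{FREQUENT_PER_STIM_PER_BLOCK} frequent-category trials, "
                    f"got {n_freq} (trials "
                    f"{[t.trial_index for t in stim_trials]})"
                )
    # First occurrence of each stimulus anywhere in the task must be frequent.
    seen: set[str] = set()
    for t in trials:
        if t.stimulus_id not in seen:
            seen.add(t.stimulus_id)
            spec = STIMULI.get(t.stimulus_id)
            if spec is not None and t.assigned_category != spec.frequent_category:
                violations.append(
                    f"first occurrence of {t.stimulus_id} (trial {t.trial_index}) "
                    "is not frequent-category"
                )
    return violations
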