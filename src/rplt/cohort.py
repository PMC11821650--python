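"""Synthetic study generator: agents, sessions, covariates, and event streams.

The generator emits a complete stand-in for the study's deposited data --
trial-by-trial task logs produced by Q-learning agents, a clinical covariate
table, and a dated event stream -- with the statistical structure the analysis
assumes.  Group profiles anchor the agent-parameter and covariate
distributions to the observed per-outcome-group summary statistics: the
ambiguous-outcome value R0 averages +0.13 in sessions followed by no suicidal
event, +0.22 before another suicide-related event, and -0.24 before an actual
attempt, with the corresponding learning-rate, explore/exploit and
suicidal-ideation profiles.

Group membership is assigned per session, not per subject: the analysis unit
is the session, and the same individual can present an attempt-like profile
before an attempt and an unremarkable one otherwise.  Default shape follows
the study: 58 subjects, 118 classifiable sessions split 100/13/5 across
noSE/OtherSE/ASA, 1-5 sessions per subject.  Consecutive sessions are spaced
at least 91 days apart so each planned event lands only in its own session's
90-day window and every intended label is recovered exactly by the
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior, fitting, outcomes, risk
from .fitting import FitConfig, fit_session, fits_frame
from .model import PARAM_BOUNDS, AgentParams, simulate_agent
from .task import TrialSchedule, canonical_schedule

__all__ = [
    "GroupProfile",
    "CohortConfig",
    "CohortBundle",
    "DEFAULT_PROFILES",
    "sample_session_truth",
    "generate_cohort",
    "end_to_end",
]


@dataclass(frozen=True)
class GroupProfile:
    """Generating distribution for sessions with a given upcoming outcome."""

    label: str
    lr_plus: tuple[float, float]  # (mean, sd)
    lr_minus: tuple[float, float]
    beta: tuple[float, float]
    r0: tuple[float, float]
    ssi: tuple[float, float]
    session_share: float


#: Per-outcome-group parameter and covariate profiles (observed group means
#: and SDs) with shares matching the 100/13/5 split of 118 sessions.
DEFAULT_PROFILES: tuple[GroupProfile, ...] = (
    GroupProfile(
        label="noSE",
        lr_plus=(0.33, 0.35),
        lr_minus=(0.40, 0.38),
        beta=(0.52, 0.29),
        r0=(0.13, 0.71),
        ssi=(7.3, 9.2),
        session_share=100 / 118,
    ),
    GroupProfile(
        label="OtherSE",
        lr_plus=(0.24, 0.30),
        lr_minus=(0.37, 0.38),
        beta=(0.46, 0.28),
        r0=(0.22, 0.60),
        ssi=(6.0, 8.6),
        session_share=13 / 118,
    ),
    GroupProfile(
        label="ASA",
        lr_plus=(0.38, 0.39),
        lr_minus=(0.20, 0.17),
        beta=(0.32, 0.18),
        r0=(-0.24, 0.71),
        ssi=(15.2, 8.4),
        session_share=5 / 118,
    ),
)


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 58
    n_sessions: int = 118
    sessions_per_subject: tuple[int, int] = (1, 5)
    profiles: tuple[GroupProfile, ...] = DEFAULT_PROFILES
    master_seed: int = 20240101
    first_session_date: date = date(2019, 6, 1)
    #: days between a subject's consecutive sessions (min must exceed 90 so
    #: event plans cannot bleed across windows)
    intersession_gap: tuple[int, int] = (91, 180)
    follow_up_days: int = 365  # study end relative to a subject's last session
    include_practice: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.sessions_per_subject
        if not (1 <= lo <= hi):
            raise ValueError("sessions_per_subject must satisfy 1 <= lo <= hi")
        if self.n_sessions < self.n_subjects * lo or self.n_sessions > (
            self.n_subjects * hi
        ):
            raise ValueError("n_sessions incompatible with sessions_per_subject")
        shares = sum(p.session_share for p in self.profiles)
        if abs(shares - 1.0) > 1e-9:
            raise ValueError("session shares must sum to 1")


@dataclass
class CohortBundle:
    """Everything the pipeline consumes, plus the generating truth."""

    trial_logs: pd.DataFrame
    clinical: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _truncnorm(mean: float, sd: float, lo: float, hi: float, rng) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(
        stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
    )


def sample_session_truth(
    group: GroupProfile, rng: np.random.Generator
) -> tuple[AgentParams, float, dict]:
    """Draw one session's generating parameters, SSI, and event plan.

    Parameters come from normals truncated to the model bounds (means shift
    slightly from the nominal profile means under truncation; the truth table
    records realized values).  SSI is normal floored at 0.  The event plan
    places one qualifying event uniformly on days 1-90 after the session for
    ASA/OtherSE groups and none for noSE.
    """
    params = AgentParams(
        lr_plus=_truncnorm(*group.lr_plus, *PARAM_BOUNDS["lr_plus"], rng),
        lr_minus=_truncnorm(*group.lr_minus, *PARAM_BOUNDS["lr_minus"], rng),
        beta=_truncnorm(*group.beta, *PARAM_BOUNDS["beta"], rng),
        r0=_truncnorm(*group.r0, *PARAM_BOUNDS["r0"], rng),
    )
    ssi = max(0.0, float(rng.normal(*group.ssi)))
    plan: dict = {"label": group.label, "event_type": None, "event_day": None}
    if group.label == "ASA":
        plan["event_type"] = "ASA"
        plan["event_day"] = int(rng.integers(1, outcomes.WINDOW_DAYS + 1))
    elif group.label == "OtherSE":
        plan["event_type"] = str(
            rng.choice(sorted(outcomes.OTHER_SE_EVENTS))
        )
        plan["event_day"] = int(rng.integers(1, outcomes.WINDOW_DAYS + 1))
    return params, ssi, plan


def _allocate_sessions(config: CohortConfig, rng) -> list[int]:
    """Sessions per subject: start at the minimum, sprinkle the remainder."""
    lo, hi = config.sessions_per_subject
    counts = [lo] * config.n_subjects
    remaining = config.n_sessions - lo * config.n_subjects
    while remaining > 0:
        i = int(rng.integers(config.n_subjects))
        if counts[i] < hi:
            counts[i] += 1
            remaining -= 1
    return counts


def _allocate_groups(config: CohortConfig, rng) -> list[str]:
    """Exact per-group session counts by largest remainder, shuffled."""
    raw = [p.session_share * config.n_sessions for p in config.profiles]
    base = [int(np.floor(x)) for x in raw]
    short = config.n_sessions - sum(base)
    order = np.argsort([b - x for b, x in zip(base, raw)])  # largest remainder
    for k in range(short):
        base[order[k]] += 1
    labels: list[str] = []
    for p, n in zip(config.profiles, base):
        labels.extend([p.label] * n)
    rng.shuffle(labels)
    return labels


def _prior_asa_count(rng) -> int:
    """Lifetime prior attempts: ~21.7% zero, 33.3% one, 45.0% two or more."""
    u = rng.random()
    if u < 0.217:
        return 0
    if u < 0.217 + 0.333:
        return 1
    return int(rng.integers(2, 6))


def generate_cohort(config: CohortConfig | None = None) -> CohortBundle:
    """Generate the full synthetic study bundle, reproducible from the seed."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.master_seed)
    schedule = canonical_schedule()
    profile_by_label = {p.label: p for p in config.profiles}

    session_counts = _allocate_sessions(config, rng)
    group_labels = _allocate_groups(config, rng)

    logs: list[pd.DataFrame] = []
    clinical_rows: list[dict] = []
    event_rows: list[dict] = []
    truth_rows: list[dict] = []
    session_no = 0
    for subj_idx, n_sess in enumerate(session_counts):
        subject_id = f"SUBJ{subj_idx + 1:03d}"
        n_prior = _prior_asa_count(rng)
        start = config.first_session_date + timedelta(
            days=int(rng.integers(0, 180))
        )
        session_date = start
        last_date = start
        for k in range(n_sess):
            if k > 0:
                gap = int(rng.integers(*config.intersession_gap))
                session_date = session_date + timedelta(days=gap)
            last_date = session_date
            session_id = f"SESS{session_no + 1:04d}"
            group = profile_by_label[group_labels[session_no]]
            params, ssi, plan = sample_session_truth(group, rng)
            log = simulate_agent(
                schedule,
                params,
                seed=int(rng.integers(2**31)),
                session_id=session_id,
                subject_id=subject_id,
                include_practice=config.include_practice,
            )
            logs.append(log)
            clinical_rows.append(
                {
                    "session_id": session_id,
                    "subject_id": subject_id,
                    "session_date": session_date.isoformat(),
                    "ssi_at_testing": round(ssi, 1),
                    "n_prior_asa": n_prior,
                }
            )
            if plan["event_type"] is not None:
                event_rows.append(
                    {
                        "subject_id": subject_id,
                        "event_date": (
                            session_date + timedelta(days=plan["event_day"])
                        ).isoformat(),
                        "event_type": plan["event_type"],
                    }
                )
            truth_rows.append(
                {
                    "session_id": session_id,
                    "subject_id": subject_id,
                    "intended_label": group.label,
                    "true_lr_plus": params.lr_plus,
                    "true_lr_minus": params.lr_minus,
                    "true_beta": params.beta,
                    "true_r0": params.r0,
                }
            )
            session_no += 1
        event_rows.append(
            {
                "subject_id": subject_id,
                "event_date": (
                    last_date + timedelta(days=config.follow_up_days)
                ).isoformat(),
                "event_type": "study_end",
            }
        )
    bundle = CohortBundle(
        trial_logs=pd.concat(logs, ignore_index=True),
        clinical=pd.DataFrame(clinical_rows),
        events=pd.DataFrame(event_rows),
        truth=pd.DataFrame(truth_rows),
        manifest={
            "master_seed": config.master_seed,
            "n_subjects": config.n_subjects,
            "n_sessions": config.n_sessions,
            "schedule_id": schedule.schedule_id,
            "group_shares": {
                p.label: p.session_share for p in config.profiles
            },
        },
    )
    return bundle


def end_to_end(
    bundle: CohortBundle,
    fit_config: FitConfig | None = None,
    schedule: TrialSchedule | None = None,
) -> dict:
    """Run the whole pipeline: clean, summarize, fit, classify, model.

    Returns a dict with the session-summary table, fit-results table, outcome
    table, the analysis table joining them, the three odds-ratio tables, and a
    small run report (seeds, counts).
    """
    fit_config = fit_config or FitConfig()
    summaries: list[behavior.SessionSummary] = []
    session_ids: list[str] = []
    fit_results: list[fitting.FitResult] = []
    for session_id, raw in bundle.trial_logs.groupby("session_id", sort=True):
        cleaned, flags = behavior.clean_session(raw)
        if flags.noncompliant:
            continue
        summaries.append(behavior.summarize_session(cleaned, flags))
        session_ids.append(str(session_id))
        fit_results.append(fit_session(cleaned, fit_config))
    summary_df = behavior.summaries_frame(summaries)
    fits_df = fits_frame(session_ids, fit_results)

    sessions = bundle.clinical[["session_id", "subject_id", "session_date"]]
    outcome_df, counts = outcomes.build_outcome_table(sessions, bundle.events)

    analysis = (
        outcome_df.merge(bundle.clinical, on=["session_id", "subject_id"])
        .merge(summary_df, on="session_id")
        .merge(fits_df, on="session_id")
    )
    analysis = analysis[analysis["label"] != "unclassifiable"]

    or_tables = {
        "model_1": risk.model_1_behavior(analysis).or_table,
        "model_2": risk.model_2_adjusted(analysis).or_table,
        "model_3": risk.model_3_r0(analysis).or_table,
    }
    report = {
        "n_sessions_input": int(bundle.trial_logs["session_id"].nunique()),
        "n_sessions_analyzed": int(len(analysis)),
        "outcome_counts": counts,
        "fit_seed": fit_config.seed,
        "n_starts": fit_config.n_starts,
        "manifest": bundle.manifest,
    }
    return {
        "summaries": summary_df,
        "fits": fits_df,
        "outcomes": outcome_df,
        "analysis": analysis,
        "or_tables": or_tables,
        "report": report,
    }
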