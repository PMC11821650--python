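"""Prospective 90-day outcome classification with censoring.

Each testing session is labeled by what happened in the 90 days that followed:
``ASA`` if there was at least one actual suicide attempt in the window,
``OtherSE`` if there was no attempt but at least one other suicide-related
event (interrupted/aborted attempt, preparatory behavior, or an
ideation-related hospitalization), ``noSE`` if neither occurred and the full
window was observed, and ``unclassifiable`` if follow-up ended inside the
window with no qualifying event before censoring.  The labels are mutually
exclusive with strict precedence ASA > OtherSE > noSE.

The window convention is half-open on the left and closed at day 90:
``(session_date, session_date + 90 days]``.  Events on the day of testing
belong to the preceding clinical state and do not qualify; a flag switches
this if day-0 events should count.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import pandas as pd

__all__ = [
    "EVENT_TYPES",
    "OTHER_SE_EVENTS",
    "CENSOR_EVENTS",
    "WINDOW_DAYS",
    "OutcomeLabel",
    "classify_session",
    "follow_up_end_by_subject",
    "build_outcome_table",
]

WINDOW_DAYS = 90

OTHER_SE_EVENTS = frozenset(
    {"interrupted_aborted_attempt", "preparatory_behavior", "SI_hospitalization"}
)
CENSOR_EVENTS = frozenset({"censor_death", "censor_withdrawal", "study_end"})
EVENT_TYPES = frozenset({"ASA"}) | OTHER_SE_EVENTS | CENSOR_EVENTS

LABELS = ("ASA", "OtherSE", "noSE", "unclassifiable")


@dataclass(frozen=True)
class OutcomeLabel:
    session_id: str
    label: str
    qualifying_event_date: date | None = None


def _as_date(x) -> date:
    if isinstance(x, date) and not isinstance(x, pd.Timestamp):
        return x
    return pd.Timestamp(x).date()


def classify_session(
    session_date,
    events: pd.DataFrame,
    follow_up_end,
    session_id: str = "",
    include_day0: bool = False,
) -> OutcomeLabel:
    """Label one session from its subject's dated events.

    Parameters
    ----------
    session_date
        Date of the testing session.
    events
        This subject's events: columns ``event_date``, ``event_type``.
    follow_up_end
        Last observable date for this subject (min of censor dates and study
        end).  Events dated after it raise a data-consistency error.
    include_day0
        If True the window includes the session day itself.
    """
    session_date = _as_date(session_date)
    follow_up_end = _as_date(follow_up_end)
    start = session_date if include_day0 else session_date + timedelta(days=1)
    end = session_date + timedelta(days=WINDOW_DAYS)

    qualifying_asa: date | None = None
    qualifying_other: date | None = None
    for _, row in events.iterrows():
        etype = str(row["event_type"])
        if etype not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {etype!r}")
        if etype in CENSOR_EVENTS:
            continue
        edate = _as_date(row["event_date"])
        if edate > follow_up_end:
            raise ValueError(
                f"event {etype} on {edate} is after follow-up end {follow_up_end}"
            )
        if not (start <= edate <= end):
            continue
        if etype == "ASA":
            if qualifying_asa is None or edate < qualifying_asa:
                qualifying_asa = edate
        elif etype in OTHER_SE_EVENTS:
            if qualifying_other is None or edate < qualifying_other:
                qualifying_other = edate
    if qualifying_asa is not None:
        return OutcomeLabel(session_id, "ASA", qualifying_asa)
    if qualifying_other is not None:
        return OutcomeLabel(session_id, "OtherSE", qualifying_other)
    if follow_up_end >= end:
        return OutcomeLabel(session_id, "noSE", None)
    return OutcomeLabel(session_id, "unclassifiable", None)


def follow_up_end_by_subject(
    events: pd.DataFrame, study_end=None
) -> dict[str, date]:
    """Earliest censoring date per subject (death, withdrawal, or study end)."""
    out: dict[str, date] = {}
    for subject_id, grp in events.groupby("subject_id"):
        censor_dates = [
            _as_date(d)
            for d, t in zip(grp["event_date"], grp["event_type"])
            if t in CENSOR_EVENTS
        ]
        if study_end is not None:
            censor_dates.append(_as_date(study_end))
        if not censor_dates:
            raise ValueError(
                f"subject {subject_id!r} has no censoring/study-end event and no "
                "study_end was given"
            )
        out[str(subject_id)] = min(censor_dates)
    return out


def build_outcome_table(
    sessions: pd.DataFrame,
    events: pd.DataFrame,
    study_end=None,
    include_day0: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label every session and tally labels.

    ``sessions`` needs columns session_id, subject_id, session_date; events as
    in :func:`classify_session` plus subject_id.  Returns the outcome table
    (one row per session) and per-label counts.  Unclassifiable sessions stay
    in the table but must be excluded from downstream modeling.
    """
    if sessions["session_id"].duplicated().any():
        dupes = sessions.loc[
            sessions["session_id"].duplicated(), "session_id"
        ].tolist()
        raise ValueError(f"duplicate session_id values: {dupes}")
    fu = follow_up_end_by_subject(events, study_end=study_end)
    rows = []
    for _, s in sessions.iterrows():
        subject = str(s["subject_id"])
        sub_events = events[events["subject_id"].astype(str) == subject]
        label = classify_session(
            s["session_date"],
            sub_events,
            fu[subject],
            session_id=str(s["session_id"]),
            include_day0=include_day0,
        )
        rows.append(
            {
                "session_id": label.session_id,
                "subject_id": subject,
                "session_date": _as_date(s["session_date"]).isoformat(),
                "label": label.label,
                "qualifying_event_date": (
                    label.qualifying_event_date.isoformat()
                    if label.qualifying_event_date
                    else ""
                ),
            }
        )
    table = pd.DataFrame(rows)
    counts = {lab: int((table["label"] == lab).sum()) for lab in LABELS}
    return table, counts
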