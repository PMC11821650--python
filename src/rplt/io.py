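"""Readers and writers for the pipeline's delimited-text tables.

Everything is comma-separated UTF-8 with a header row; dates are ISO-8601.
Readers validate enumerations strictly and reject malformed rows with the
offending row named, so that a file that parses cleanly is safe for every
downstream stage.
"""

from __future__ import annotations

import pandas as pd
import yaml

from .outcomes import EVENT_TYPES, LABELS
from .task import STIMULI

__all__ = [
    "read_trial_log",
    "write_trial_log",
    "read_clinical",
    "write_clinical",
    "read_events",
    "write_events",
    "read_outcomes",
    "write_outcomes",
    "read_table",
    "write_table",
    "write_manifest",
    "read_manifest",
]

TRIAL_COLUMNS = [
    "session_id",
    "subject_id",
    "trial_index",
    "block",
    "practice_flag",
    "stimulus_id",
    "valence",
    "assigned_category",
    "response",
    "correct",
    "feedback",
    "tally_after",
    "rt_ms",
]

_PRACTICE_STIMULI = {"P1", "P2"}
_VALENCES = {"reward", "punishment"}
_CATEGORIES = {"A", "B"}
_FEEDBACK = {"reward", "punish", "none"}


def write_trial_log(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial log (may contain several sessions)."""
    df = pd.read_csv(path, dtype={"session_id": str, "subject_id": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path}: missing columns {missing}")
    df["practice_flag"] = df["practice_flag"].astype(bool)
    df["correct"] = df["correct"].astype(bool)
    valid_stim = set(STIMULI) | _PRACTICE_STIMULI
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        if row.stimulus_id not in valid_stim:
            raise ValueError(
                f"trial log {path} row {row_no}: unknown stimulus_id "
                f"{row.stimulus_id!r}"
            )
        if row.stimulus_id in _PRACTICE_STIMULI and not row.practice_flag:
            raise ValueError(
                f"trial log {path} row {row_no}: practice stimulus outside practice"
            )
        if row.valence not in _VALENCES:
            raise ValueError(
                f"trial log {path} row {row_no}: bad valence {row.valence!r}"
            )
        if row.assigned_category not in _CATEGORIES:
            raise ValueError(
                f"trial log {path} row {row_no}: bad assigned_category "
                f"{row.assigned_category!r}"
            )
        if row.response not in _CATEGORIES:
            raise ValueError(
                f"trial log {path} row {row_no}: bad response {row.response!r}"
            )
        if row.feedback not in _FEEDBACK:
            raise ValueError(
                f"trial log {path} row {row_no}: bad feedback {row.feedback!r}"
            )
    for sid, grp in df.groupby("session_id"):
        idx = grp["trial_index"].to_numpy()
        if (pd.Series(idx).duplicated()).any():
            raise ValueError(f"trial log {path} session {sid}: duplicate trial_index")
        if not (idx[1:] > idx[:-1]).all():
            raise ValueError(
                f"trial log {path} session {sid}: trial_index not strictly increasing"
            )
    return df


CLINICAL_COLUMNS = [
    "session_id",
    "subject_id",
    "session_date",
    "ssi_at_testing",
    "n_prior_asa",
]


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"session_id": str, "subject_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path}: missing columns {missing}")
    df["session_date"] = pd.to_datetime(df["session_date"], format="ISO8601").dt.date
    return df


EVENT_COLUMNS = ["subject_id", "event_date", "event_type"]


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events table {path}: missing columns {missing}")
    bad = set(df["event_type"]) - EVENT_TYPES
    if bad:
        raise ValueError(f"events table {path}: unknown event types {sorted(bad)}")
    df["event_date"] = pd.to_datetime(df["event_date"], format="ISO8601").dt.date
    return df


def write_outcomes(outcomes: pd.DataFrame, path) -> None:
    outcomes.to_csv(path, index=False)


def read_outcomes(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"session_id": str, "subject_id": str}, keep_default_na=False
    )
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise ValueError(
            f"outcome table {path}: unknown labels {sorted(bad)} (labels are "
            "case-sensitive)"
        )
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Generic writer for summary / fit-result / odds-ratio tables."""
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
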