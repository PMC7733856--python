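"""CSV schemas, validated readers/writers and trial-to-subject aggregation.

Two tables flow through the pipeline:

* the **trial table** — one row per task trial, columns exactly matching
  :class:`infoseek.cohort.TrialRecord` plus a study label;
* the **subject table** — one row per participant with factor scores,
  demographics and behavioural aggregates (seek rate, accuracies, mean
  confidence, calibrated stimulus strength, total points).

Both are plain CSV so that artifacts are diff-able and reproducible
byte-for-byte from a seed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = {
    "subject_id": str,
    "study": str,
    "block": int,
    "trial_index": int,
    "cost_points": int,
    "dot_difference": int,
    "correct_side": str,
    "initial_choice": str,
    "initial_conf_level": int,
    "initial_conf_code6": int,
    "sought": bool,
    "final_choice": str,
    "final_conf_level": int,
    "initial_correct": bool,
    "final_correct": bool,
    "points": int,
}

SUBJECT_COLUMNS = {
    "subject_id": str,
    "study": str,
    "dogmatism": float,
    "orientation": float,
    "superiority": float,
    "age": float,
    "gender": int,
    "education": int,
    "seek_rate": float,
    "initial_accuracy": float,
    "final_accuracy": float,
    "mean_confidence": float,
    "calibrated_dot_difference": int,
    "total_points": int,
}

#: Subject-table columns treated as continuous when standardizing.
CONTINUOUS_SUBJECT_COLUMNS = (
    "dogmatism",
    "orientation",
    "superiority",
    "age",
    "education",
    "seek_rate",
    "initial_accuracy",
    "final_accuracy",
    "mean_confidence",
    "total_points",
)

_BOOL_TRUE = {"true", "1", "t"}


def _coerce(df, schema, what):
    out = {}
    for col, typ in schema.items():
        s = df[col]
        try:
            if typ is bool:
                if s.dtype == object:
                    s = s.astype(str).str.lower().isin(_BOOL_TRUE)
                else:
                    s = s.astype(int).astype(bool)
            elif typ is int:
                s = s.astype(np.int64)
            elif typ is float:
                s = s.astype(float)
            else:
                s = s.astype(str)
        except (ValueError, TypeError) as exc:
            bad = next(
                (i for i, v in s.items() if not _castable(v, typ)), "<unknown>"
            )
            raise SchemaError(
                f"{what} table: column '{col}' has a bad value at row {bad}: {exc}"
            ) from exc
        out[col] = s
    return pd.DataFrame(out)


def _castable(v, typ):
    try:
        typ(v)
        return True
    except (ValueError, TypeError):
        return False


def _validate(df, schema, what):
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required columns: {missing}")
    out = _coerce(df, schema, what)
    if (out["subject_id"].str.len() == 0).any():
        raise SchemaError(f"{what} table: empty subject_id")
    return out


def validate_trials(df):
    """Coerce and validate a trial table; returns the validated copy."""
    out = _validate(df, TRIAL_COLUMNS, "trial")
    dup = out.duplicated(subset=["subject_id", "trial_index"])
    if dup.any():
        row = out.index[dup][0]
        raise SchemaError(f"trial table: duplicate (subject_id, trial_index) at row {row}")
    for col, allowed in (("cost_points", {5, 20}), ("initial_conf_level", {1, 2, 3}),
                         ("final_conf_level", {1, 2, 3})):
        bad = ~out[col].isin(allowed)
        if bad.any():
            row = out.index[bad][0]
            raise SchemaError(
                f"trial table: column '{col}' has disallowed value "
                f"{out[col].iloc[row]} at row {row}"
            )
    return out


def validate_subjects(df):
    """Coerce and validate a subject table; returns the validated copy."""
    out = _validate(df, SUBJECT_COLUMNS, "subject")
    for col in ("seek_rate", "initial_accuracy", "final_accuracy"):
        bad = (out[col] < 0) | (out[col] > 1)
        if bad.any():
            row = out.index[bad][0]
            raise SchemaError(f"subject table: '{col}' outside [0, 1] at row {row}")
    return out


def read_trials(path):
    """Read and validate a trial CSV."""
    return validate_trials(pd.read_csv(path))


def write_trials(df, path):
    """Validate and write a trial CSV (lossless round trip with read_trials)."""
    out = validate_trials(df).copy()
    for col, typ in TRIAL_COLUMNS.items():
        if typ is bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def read_subjects(path):
    """Read and validate a subject CSV."""
    return validate_subjects(pd.read_csv(path))


def write_subjects(df, path):
    """Validate and write a subject CSV."""
    validate_subjects(df).to_csv(path, index=False)


def aggregate_subjects(trials, subject_info=None):
    """Aggregate a trial table to one behavioural summary row per subject.

    Computes seek rate, initial/final accuracy, mean initial confidence
    level, calibrated dot difference and total points, then joins the
    per-subject covariates (factor scores, demographics) from
    ``subject_info`` when supplied.  Subjects present in ``subject_info``
    but with zero trials are excluded with a logged warning.
    """
    g = trials.groupby("subject_id", sort=True)
    agg = pd.DataFrame(
        {
            "subject_id": list(g.groups),
            "study": g["study"].first().to_numpy(),
            "seek_rate": g["sought"].mean().to_numpy(dtype=float),
            "initial_accuracy": g["initial_correct"].mean().to_numpy(dtype=float),
            "final_accuracy": g["final_correct"].mean().to_numpy(dtype=float),
            "mean_confidence": g["initial_conf_level"].mean().to_numpy(dtype=float),
            "calibrated_dot_difference": g["dot_difference"].first().to_numpy(dtype=np.int64),
            "total_points": g["points"].sum().to_numpy(dtype=np.int64),
        }
    )
    if subject_info is not None:
        info = subject_info.copy()
        dropped = set(info["subject_id"]) - set(agg["subject_id"])
        if dropped:
            logger.warning("excluding %d subjects with zero trials: %s",
                           len(dropped), sorted(dropped))
        if "study" in info.columns:
            info = info.drop(columns=["study"])
        agg = info.merge(agg, on="subject_id", how="inner")
    cols = [c for c in SUBJECT_COLUMNS if c in agg.columns]
    extra = [c for c in agg.columns if c not in cols]
    return agg[cols + extra]
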