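"""Trial-table I/O, behavioral preprocessing, and baseline-relative measures.

The trial CSV dialect (UTF-8, header required, `NA` for missing):

    participant_id, session (1|2), condition (Neutral|Warm),
    moment (Baseline|Begin|End), task (timing|choice), rt_s,
    response (target|foil|NA), correct (0|1|NA), reproduction_s
    (NA for choice), deadline_s, missed_deadline (0|1|NA)

Preprocessing order is fixed: validate -> filter fast RTs -> log
transform -> baseline-relative measures.  Choice RTs faster than 200 ms
are excluded (strictly: rt < 0.2 s; a trial at exactly 200 ms is kept)
before model fitting; RTs are natural-log transformed for descriptive
analyses; continuous measures are expressed as z-scores relative to the
same session's out-of-tub Baseline, and accuracy — where z-scoring a
proportion is not meaningful — is carried as a difference from Baseline
with the Baseline proportion available as a covariate column.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONDITIONS, MOMENTS, RESPONSES, TASKS

__all__ = [
    "COLUMNS",
    "TrialValidationError",
    "validate_trials",
    "read_trials",
    "write_trials",
    "filter_fast_rts",
    "log_transform_rts",
    "baseline_zscore",
    "accuracy_measures",
    "correlate_changes",
    "dataset_hash",
    "FAST_RT_THRESHOLD_S",
]

COLUMNS = [
    "participant_id", "session", "condition", "moment", "task", "rt_s",
    "response", "correct", "reproduction_s", "deadline_s", "missed_deadline",
]

#: fast-guess exclusion bound (200 ms), applied strictly (rt < threshold)
FAST_RT_THRESHOLD_S = 0.2

_PROVENANCE_PREFIX = "# thermolba-trials v1"


class TrialValidationError(ValueError):
    """Raised with row-level detail when a trial table is malformed."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        shown = problems[:20]
        more = f" (+{len(problems) - 20} more)" if len(problems) > 20 else ""
        super().__init__("invalid trial table:\n  " + "\n  ".join(shown) + more)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly coerce) a trial table; raises
    :class:`TrialValidationError` listing offending rows."""
    problems = []
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError([f"missing columns: {missing}"])
    df = df.copy()
    for col in ("rt_s", "reproduction_s", "deadline_s"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for i, row in enumerate(df.itertuples(index=False)):
        where = f"row {i}"
        if row.condition not in CONDITIONS:
            problems.append(f"{where}: unknown condition {row.condition!r}")
        if row.moment not in MOMENTS:
            problems.append(f"{where}: unknown moment {row.moment!r}")
        if row.task not in TASKS:
            problems.append(f"{where}: unknown task {row.task!r}")
            continue
        if row.task == "choice":
            if not (row.rt_s > 0):
                problems.append(f"{where}: choice trial needs rt_s > 0, got {row.rt_s}")
            if row.response not in RESPONSES:
                problems.append(f"{where}: unknown response {row.response!r}")
        else:  # timing
            if not (row.reproduction_s > 0):
                problems.append(
                    f"{where}: timing trial needs reproduction_s > 0, "
                    f"got {row.reproduction_s}")
    if problems:
        raise TrialValidationError(problems)
    return df


def write_trials(df: pd.DataFrame, path, provenance: str = "") -> None:
    """Write the trial CSV dialect with a provenance header comment."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{_PROVENANCE_PREFIX} {provenance}".rstrip() + "\n")
        # %.17g guarantees float64 round-trip through text
        df.to_csv(fh, index=False, columns=COLUMNS, na_rep="NA",
                  float_format="%.17g")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV.  Round-trips
    :func:`write_trials` output losslessly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, comment="#", na_values=["NA"], keep_default_na=True,
        dtype={"participant_id": str, "response": str},
        float_precision="round_trip",
    )
    df["response"] = df["response"].fillna("NA")
    return validate_trials(df)


def dataset_hash(df: pd.DataFrame) -> str:
    """Stable content hash of a trial table, recorded in fit manifests so
    model comparisons can enforce the same-data precondition."""
    sub = df[COLUMNS].copy()
    payload = sub.round(12).to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def filter_fast_rts(df: pd.DataFrame,
                    threshold_s: float = FAST_RT_THRESHOLD_S):
    """Drop choice trials with rt_s strictly below `threshold_s`.

    Returns (filtered table, report).  The report reconciles exactly:
    retained + excluded = input count, and gives per-participant
    exclusion fractions over choice trials.
    """
    if threshold_s < 0:
        raise ValueError("threshold must be >= 0")
    is_choice = df["task"] == "choice"
    fast = is_choice & (df["rt_s"] < threshold_s)
    kept = df[~fast].reset_index(drop=True)
    per_part = {}
    for pid, grp in df[is_choice].groupby("participant_id"):
        n = len(grp)
        per_part[str(pid)] = {
            "n_choice": int(n),
            "n_excluded": int((grp["rt_s"] < threshold_s).sum()),
            "fraction_excluded": float((grp["rt_s"] < threshold_s).mean())
            if n else 0.0,
        }
    report = {
        "threshold_s": float(threshold_s),
        "n_input": int(len(df)),
        "n_excluded": int(fast.sum()),
        "n_retained": int(len(kept)),
        "per_participant": per_part,
    }
    return kept, report


def log_transform_rts(df: pd.DataFrame) -> pd.DataFrame:
    """Add a natural-log RT column (`log_rt_s`), preserving the original."""
    choice = df["task"] == "choice"
    if (df.loc[choice, "rt_s"] <= 0).any():
        raise ValueError("non-positive RT encountered; validate first")
    out = df.copy()
    out["log_rt_s"] = np.where(choice, np.log(df["rt_s"]), np.nan)
    return out


def _measure_series(df: pd.DataFrame, measure: str) -> pd.Series:
    if measure == "reproduction_s":
        sub = df[df["task"] == "timing"]
        return sub["reproduction_s"]
    if measure == "log_rt_s":
        if "log_rt_s" not in df.columns:
            df = log_transform_rts(df)
        sub = df[df["task"] == "choice"]
        return sub["log_rt_s"]
    raise ValueError(f"unknown measure {measure!r}")


def baseline_zscore(df: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Per participant x condition, express the Begin/End cell mean of a
    continuous measure as a z-score relative to that session's Baseline:
    z = (cell mean - Baseline mean) / Baseline SD.

    Returns a table (participant_id, condition, moment, value).  Baseline
    rows are consumed, not emitted.  A zero-spread Baseline is an error
    naming the participant and condition.
    """
    task = "timing" if measure == "reproduction_s" else "choice"
    work = df[df["task"] == task].copy()
    if measure == "log_rt_s" and "log_rt_s" not in work.columns:
        work = log_transform_rts(work)
    col = measure
    rows = []
    for (pid, cond), grp in work.groupby(["participant_id", "condition"]):
        base = grp.loc[grp["moment"] == "Baseline", col]
        if len(base) < 2 or np.isclose(base.std(ddof=1), 0.0):
            raise ValueError(
                f"zero or undefined Baseline spread for participant {pid}, "
                f"condition {cond}")
        mu, sd = base.mean(), base.std(ddof=1)
        for mom in ("Begin", "End"):
            cell = grp.loc[grp["moment"] == mom, col]
            if len(cell) == 0:
                continue
            rows.append({"participant_id": pid, "condition": cond,
                         "moment": mom, "value": (cell.mean() - mu) / sd})
    return pd.DataFrame(rows)


def accuracy_measures(df: pd.DataFrame) -> pd.DataFrame:
    """Per-cell accuracy with the session Baseline proportion as a
    covariate column and the difference from Baseline for Begin/End.

    Returns (participant_id, condition, moment, accuracy,
    baseline_accuracy, diff_from_baseline); cells without trials are
    flagged by absence, never imputed.
    """
    work = df[df["task"] == "choice"]
    rows = []
    for (pid, cond), grp in work.groupby(["participant_id", "condition"]):
        base = grp.loc[grp["moment"] == "Baseline", "correct"]
        base_acc = float(base.mean()) if len(base) else np.nan
        for mom in MOMENTS:
            cell = grp.loc[grp["moment"] == mom, "correct"]
            if len(cell) == 0:
                continue
            acc = float(cell.mean())
            rows.append({
                "participant_id": pid, "condition": cond, "moment": mom,
                "accuracy": acc, "baseline_accuracy": base_acc,
                "diff_from_baseline": acc - base_acc
                if mom != "Baseline" and np.isfinite(base_acc) else
                (0.0 if mom == "Baseline" and np.isfinite(base_acc) else np.nan),
            })
    return pd.DataFrame(rows)


def correlate_changes(x: pd.DataFrame, y: pd.DataFrame,
                      value_x: str = "value", value_y: str = "value",
                      grouping: str = "condition") -> pd.DataFrame:
    """Pearson correlations between two baseline-relative measures.

    Pairs are aligned on (participant_id, condition, moment); one row of
    output per level of `grouping` plus a pooled row.  Zero variance in
    either variable gives an undefined (NaN) r, flagged in the `defined`
    column rather than silently dropped.
    """
    merged = pd.merge(
        x.rename(columns={value_x: "_x"}),
        y.rename(columns={value_y: "_y"}),
        on=["participant_id", "condition", "moment"],
    ).dropna(subset=["_x", "_y"])
    rows = []
    groups = [("pooled", merged)]
    if grouping:
        groups += list(merged.groupby(grouping))
    for name, grp in groups:
        if len(grp) < 3:
            rows.append({"group": str(name), "n": len(grp), "r": np.nan,
                         "p": np.nan, "defined": False})
            continue
        if np.isclose(grp["_x"].std(ddof=1), 0) or \
                np.isclose(grp["_y"].std(ddof=1), 0):
            rows.append({"group": str(name), "n": len(grp), "r": np.nan,
                         "p": np.nan, "defined": False})
            continue
        r, p = stats.pearsonr(grp["_x"], grp["_y"])
        rows.append({"group": str(name), "n": len(grp), "r": float(r),
                     "p": float(p), "defined": True})
    return pd.DataFrame(rows)
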