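"""Behavioral and molecular endpoint derivations.

Pure tabular transforms computed before any inferential statistics: knee
swelling difference scores (post-injection minus baseline, mm), trapezoidal
area under a behavioral time course, log10 transformation of von Frey
withdrawal thresholds, comparative-CT (2^-ddCT) relative expression against
a reference gene and control group, and mean +/- SEM group summaries.
Inferential tests (RM-ANOVA, post-tests, Mann-Whitney) are left to standard
statistical routines; these functions produce the tidy endpoint tables they
consume.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "swelling_difference",
    "swelling_difference_table",
    "timecourse_auc",
    "timecourse_auc_table",
    "log_thresholds",
    "relative_expression",
    "group_summary",
]


def swelling_difference(post_mm: float, baseline_mm: float) -> float:
    """Swelling difference score: post-injection minus baseline (mm)."""
    if post_mm is None or baseline_mm is None or np.isnan(post_mm) or np.isnan(baseline_mm):
        raise ValueError("both post and baseline measurements are required")
    return float(post_mm - baseline_mm)


def swelling_difference_table(
    timecourse: pd.DataFrame, baseline_time: float | None = None
) -> pd.DataFrame:
    """Per-subject difference scores against the baseline timepoint.

    ``baseline_time`` defaults to each subject's earliest timepoint.  The
    baseline row itself is kept (score 0) so downstream AUC sees the full
    course.
    """
    out = []
    for sid, grp in timecourse.groupby("subject_id", sort=False):
        grp = grp.sort_values("time")
        t0 = baseline_time if baseline_time is not None else grp["time"].iloc[0]
        base = grp.loc[grp["time"] == t0, "value"]
        if base.empty:
            raise ValueError(f"subject {sid!r} has no baseline at t={t0}")
        b = float(base.iloc[0])
        g = grp.copy()
        g["value"] = [swelling_difference(v, b) for v in grp["value"]]
        out.append(g)
    return pd.concat(out, ignore_index=True)


def timecourse_auc(
    times: Sequence[float],
    values: Sequence[float],
    subtract_baseline: bool = False,
) -> float:
    """Trapezoidal area under a measured time course.

    Integrates the raw values over the time axis including the baseline
    timepoint (no baseline anchoring); with ``subtract_baseline`` the first
    value is subtracted from the whole series first.  Units are
    measurement x time (e.g. mm x days, g x weeks).
    """
    t = np.asarray(list(times), dtype=float)
    v = np.asarray(list(values), dtype=float)
    if t.size < 2:
        raise ValueError("at least 2 timepoints are required for an AUC")
    if t.size != v.size:
        raise ValueError("times and values must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if subtract_baseline:
        v = v - v[0]
    return float(np.trapezoid(v, t))


def timecourse_auc_table(
    timecourse: pd.DataFrame, subtract_baseline: bool = False
) -> pd.DataFrame:
    """Per-subject AUC from a tidy (subject_id, group, time, value) table."""
    rows = []
    for (sid, group), grp in timecourse.groupby(["subject_id", "group"], sort=False):
        grp = grp.sort_values("time")
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "auc": timecourse_auc(
                    grp["time"], grp["value"], subtract_baseline=subtract_baseline
                ),
            }
        )
    return pd.DataFrame(rows)


def log_thresholds(thresholds_g: Sequence[float], base: float = 10.0) -> np.ndarray:
    """Log-transform withdrawal thresholds (log10 by convention)."""
    x = np.asarray(list(thresholds_g), dtype=float)
    if np.any(x <= 0):
        raise ValueError("withdrawal thresholds must be positive")
    return np.log(x) / np.log(base)


def relative_expression(records: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Comparative-CT relative quantification (2^-ddCT) per sample.

    ``records`` needs columns ``sample_id``, ``group``, ``ct_target``,
    ``ct_reference``.  dCT = CT_target - CT_reference; ddCT = dCT minus the
    mean dCT of the control group; fold change = 2^-ddCT.
    """
    req = {"sample_id", "group", "ct_target", "ct_reference"}
    missing = req - set(records.columns)
    if missing:
        raise KeyError(f"missing column(s): {sorted(missing)}")
    if records[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing CT value(s)")
    ctrl = records[records["group"] == control_group]
    if ctrl.empty:
        raise ValueError(f"control group {control_group!r} is empty")
    out = records.copy()
    out["dct"] = out["ct_target"] - out["ct_reference"]
    ctrl_mean = float(out.loc[out["group"] == control_group, "dct"].mean())
    out["ddct"] = out["dct"] - ctrl_mean
    out["fold_change"] = 2.0 ** (-out["ddct"])
    return out


def group_summary(
    table: pd.DataFrame, value_col: str = "value", group_col: str = "group"
) -> pd.DataFrame:
    """Mean +/- SEM per group; SEM = sample SD / sqrt(n), missing for n = 1."""
    rows = []
    for group, grp in table.groupby(group_col, sort=True):
        v = grp[value_col].to_numpy(dtype=float)
        if v.size == 0:
            raise ValueError(f"group {group!r} is empty")
        sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
        rows.append(
            {group_col: group, "n": v.size, "mean": float(v.mean()), "sem": sem}
        )
    return pd.DataFrame(rows)
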