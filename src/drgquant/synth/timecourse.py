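"""Synthetic behavioral time-course tables.

Emulates repeated per-subject measurements over a study (knee swelling in
mm, knee-withdrawal force in g capped by the assay maximum, or hind-paw
withdrawal thresholds in g): each observation is group mean trajectory +
a per-subject random offset + Gaussian measurement noise.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["generate_timecourse"]


def generate_timecourse(
    n_subjects: int | Mapping[str, int],
    timepoints: Sequence[float],
    group_effects: Mapping[str, Sequence[float]],
    noise_sd: float = 0.0,
    subject_sd: float = 0.0,
    seed: int = 0,
    ceiling: float | None = None,
) -> pd.DataFrame:
    """Draw a tidy time-course table.

    Parameters
    ----------
    n_subjects
        Subjects per group (one integer for all groups, or per-group map).
    timepoints
        Strictly increasing measurement times (days or weeks); >= 2 needed.
    group_effects
        Group label -> mean trajectory (one value per timepoint).
    noise_sd, subject_sd
        SD of per-observation noise and of the per-subject constant offset.
    ceiling
        Optional assay maximum (e.g. 450 g for knee-withdrawal force);
        observations are clipped to it.

    Returns
    -------
    DataFrame with columns ``subject_id``, ``group``, ``time``, ``value``.
    """
    t = np.asarray(list(timepoints), dtype=float)
    if t.size < 2:
        raise ValueError("at least 2 timepoints are required")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if not group_effects:
        raise ValueError("at least one group is required")
    rng = np.random.default_rng(seed)
    rows = []
    for group, traj in group_effects.items():
        traj = np.asarray(list(traj), dtype=float)
        if traj.size != t.size:
            raise ValueError(
                f"group {group!r} trajectory length {traj.size} != "
                f"{t.size} timepoints"
            )
        n = n_subjects[group] if isinstance(n_subjects, Mapping) else int(n_subjects)
        for s in range(n):
            offset = rng.normal(0.0, subject_sd) if subject_sd > 0 else 0.0
            noise = rng.normal(0.0, noise_sd, size=t.size) if noise_sd > 0 else 0.0
            values = traj + offset + noise
            if ceiling is not None:
                values = np.minimum(values, ceiling)
            for ti, v in zip(t, values):
                rows.append(
                    {
                        "subject_id": f"{group}_s{s}",
                        "group": group,
                        "time": float(ti),
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows)
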