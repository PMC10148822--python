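"""Per-cell marker combination quantification for RNAscope-style tables.

Each counted neuron is positive or negative for every probe, so a k-probe
panel partitions the cells into the 2^k combination lattice (including the
all-negative class).  Quantities mirror how multiplexed ISH sections are
reported: raw counts and percent-of-whole per combination, nested
per-section -> per-animal aggregation (sections averaged within each
animal, then mean +/- SEM across animals), and relative-frequency diameter
distributions per cell subset compared pairwise by the two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from itertools import combinations as _combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from ..synth.markers import combination_key

__all__ = [
    "classify_combinations",
    "aggregate_nested",
    "diameter_distributions",
]


def _lattice_keys(probes: Sequence[str]) -> list[str]:
    """All 2^k combination keys, triple-first ordering within each size."""
    keys = []
    for r in range(len(probes), -1, -1):
        for combo in _combinations(probes, r):
            keys.append(combination_key(combo))
    return keys


def _check_probes(table: pd.DataFrame, probes: Sequence[str]) -> None:
    missing = [p for p in probes if p not in table.columns]
    if missing:
        raise KeyError(f"probe column(s) not in table: {missing}")


def _assign_combination(table: pd.DataFrame, probes: Sequence[str]) -> pd.Series:
    pos = table[list(probes)].astype(bool)
    return pos.apply(
        lambda row: combination_key(tuple(p for p in probes if row[p])), axis=1
    )


def classify_combinations(table: pd.DataFrame, probes: Sequence[str]) -> pd.DataFrame:
    """Count cells per positivity combination, pooled over the whole table.

    Returns one row per combination of the full 2^k lattice (all-negative
    reported as ``"none"``) with ``count`` and ``percent_of_whole``; counts
    sum to the number of cells and percents to 100.
    """
    _check_probes(table, probes)
    combo = _assign_combination(table, probes)
    n = len(table)
    counts = combo.value_counts()
    rows = []
    for key in _lattice_keys(probes):
        c = int(counts.get(key, 0))
        rows.append(
            {
                "combination": key,
                "count": c,
                "percent_of_whole": 100.0 * c / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def aggregate_nested(
    table: pd.DataFrame, probes: Sequence[str], level: str = "animal"
) -> pd.DataFrame:
    """Nested percent-of-whole aggregation with mean +/- SEM across units.

    With ``level="animal"`` (the reporting convention for sectioned tissue),
    percents are computed within each section, sections are averaged within
    each animal, and the mean and SEM (sample SD / sqrt(n_animals)) are
    taken across animals.  With ``level="section"`` each section is a unit.
    SEM is reported missing (NaN) when only one unit exists.

    Returns one row per combination with columns ``mean_percent``,
    ``sem_percent``, ``n_units``.
    """
    _check_probes(table, probes)
    if level not in ("animal", "section"):
        raise ValueError("level must be 'animal' or 'section'")
    if table.empty:
        raise ValueError("empty marker table")

    def section_percents(sec: pd.DataFrame) -> pd.Series:
        out = classify_combinations(sec, probes)
        return out.set_index("combination")["percent_of_whole"]

    per_section = (
        table.groupby(["animal_id", "section_id"], sort=True)
        .apply(section_percents, include_groups=False)
    )
    if level == "animal":
        sizes = table.groupby("animal_id")["cell_id"].count()
        if (sizes == 0).any():
            raise ValueError("animal with zero counted cells")
        per_unit = per_section.groupby("animal_id").mean()
    else:
        per_unit = per_section.droplevel("animal_id")
    n_units = len(per_unit)
    mean = per_unit.mean(axis=0)
    sem = (
        per_unit.std(axis=0, ddof=1) / np.sqrt(n_units)
        if n_units > 1
        else pd.Series(np.nan, index=mean.index)
    )
    out = pd.DataFrame(
        {"mean_percent": mean, "sem_percent": sem, "n_units": n_units}
    )
    out = out.reindex(_lattice_keys(probes))
    out.index.name = "combination"
    return out.reset_index()


def diameter_distributions(
    table: pd.DataFrame,
    subsets: dict[str, dict[str, bool]],
    bin_edges: np.ndarray,
    probes: Sequence[str] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Diameter histograms per cell subset plus pairwise KS comparisons.

    Parameters
    ----------
    subsets
        Subset name -> positivity filter, e.g.
        ``{"Piezo2 only": {"Piezo2": True, "Scn10a": False, "Ntrk1": False}}``.
        A cell belongs to a subset when every listed probe matches.
    bin_edges
        Strictly increasing diameter bin edges (um).
    probes
        Only used for column validation; defaults to the probes named in
        the filters.

    Returns
    -------
    histograms
        Subset name -> relative-frequency DataFrame (frequencies sum to 1).
    ks_table
        One row per subset pair: KS statistic ``D`` (sup ECDF distance) and
        two-tailed asymptotic p-value.  Subsets need >= 2 cells for KS.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing, length >= 2")
    used = sorted({p for f in subsets.values() for p in f})
    _check_probes(table, probes if probes is not None else used)

    diam: dict[str, np.ndarray] = {}
    hists: dict[str, pd.DataFrame] = {}
    for name, flt in subsets.items():
        mask = np.ones(len(table), dtype=bool)
        for probe, wanted in flt.items():
            mask &= table[probe].astype(bool).to_numpy() == wanted
        d = table.loc[mask, "diameter_um"].to_numpy(dtype=float)
        if d.size == 0:
            raise ValueError(f"subset {name!r} is empty")
        diam[name] = d
        counts, _ = np.histogram(np.clip(d, edges[0], np.nextafter(edges[-1], 0)),
                                 bins=edges)
        hists[name] = pd.DataFrame(
            {
                "bin_left": edges[:-1],
                "bin_right": edges[1:],
                "count": counts,
                "frequency": counts / d.size,
            }
        )

    rows = []
    for a, b in _combinations(subsets, 2):
        if diam[a].size < 2 or diam[b].size < 2:
            raise ValueError(f"subset {a!r} or {b!r} has < 2 cells for KS")
        res = ks_2samp(diam[a], diam[b], alternative="two-sided", method="asymp")
        rows.append(
            {
                "subset_a": a,
                "subset_b": b,
                "n_a": diam[a].size,
                "n_b": diam[b].size,
                "ks_statistic": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
    return hists, pd.DataFrame(rows)
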