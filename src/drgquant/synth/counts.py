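"""Synthetic gene x cell count matrices with constructed QC structure.

Emulates a droplet scRNA-seq expression matrix of dissociated DRG cells:
sparse non-negative integer counts, per-cell feature counts and
mitochondrial percentages, a configurable fraction of low-quality cells
built to fail the standard QC filter (few detected genes and/or a high
mitochondrial fraction), and a set of marker genes whose joint
expression pattern follows a configurable combination lattice so that
threshold co-expression fractions have known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import scipy.sparse as sp

from .markers import _normalize_lattice, combination_key

__all__ = ["CountSimConfig", "generate_count_matrix", "DEFAULT_SCRNA_LATTICE"]

#: Default marker-gene lattice for the scRNA-seq emulation; anchored so the
#: Scn10a-conditioned Piezo2 & Ntrk1 co-expression fraction is 38% of
#: Scn10a-expressing cells (0.19 / 0.50).
DEFAULT_SCRNA_LATTICE: dict[str, float] = {
    "Scn10a+Piezo2+Ntrk1": 0.19,
    "Scn10a+Piezo2": 0.12,
    "Scn10a+Ntrk1": 0.07,
    "Scn10a": 0.12,
    "Piezo2+Ntrk1": 0.10,
    "Piezo2": 0.20,
    "Ntrk1": 0.05,
    "none": 0.15,
}


@dataclass(frozen=True)
class CountSimConfig:
    """Study conditions for a synthetic count matrix.

    ``low_quality_fraction`` cells are built to fail QC, split evenly
    between low-feature cells (50-200 detected genes, below the > 200
    retention rule) and high-mito cells (20-50% mitochondrial counts,
    above the < 15% retention rule).  Passing cells are built with
    ``features_pass`` detected genes and a 2-10% mitochondrial fraction.
    """

    n_genes: int = 1500
    n_cells: int = 1000
    low_quality_fraction: float = 0.2
    features_pass: tuple[int, int] = (350, 900)
    features_fail: tuple[int, int] = (50, 200)
    mito_frac_pass: tuple[float, float] = (0.02, 0.10)
    mito_frac_fail: tuple[float, float] = (0.20, 0.50)
    marker_genes: tuple[str, ...] = ("Scn10a", "Piezo2", "Ntrk1")
    marker_combination_probabilities: dict = field(
        default_factory=lambda: dict(DEFAULT_SCRNA_LATTICE)
    )
    n_mito_genes: int = 13
    mito_prefix: str = "mt-"
    background_mean: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cells <= 0:
            raise ValueError("n_genes and n_cells must be positive")
        if not 0.0 <= self.low_quality_fraction <= 1.0:
            raise ValueError("low_quality_fraction must lie in [0, 1]")
        needed = self.features_pass[1] + self.n_mito_genes + len(self.marker_genes)
        if self.n_genes < needed:
            raise ValueError(
                f"n_genes={self.n_genes} too small for features_pass up to "
                f"{self.features_pass[1]} plus markers and mito genes"
            )
        _normalize_lattice(self.marker_combination_probabilities, self.marker_genes)


def expected_coexpression_fraction(
    config: CountSimConfig,
    genes: tuple[str, ...],
    condition_on: str | None = None,
) -> float:
    """Ground-truth fraction of cells expressing all ``genes``.

    Computed from the configured combination lattice; with ``condition_on``
    the fraction is taken among cells expressing the conditioning gene.
    """
    lattice = _normalize_lattice(
        config.marker_combination_probabilities, config.marker_genes
    )
    num = sum(p for c, p in lattice.items() if set(genes) <= c)
    if condition_on is None:
        return num
    den = sum(p for c, p in lattice.items() if condition_on in c)
    if den == 0:
        raise ValueError(f"no lattice mass on {condition_on!r}+ cells")
    num = sum(p for c, p in lattice.items() if set(genes) <= c and condition_on in c)
    return num / den


def generate_count_matrix(config: CountSimConfig) -> ad.AnnData:
    """Simulate a sparse count matrix as an AnnData (cells x genes).

    ``obs`` carries per-cell ground truth: ``qc_pass_truth`` (constructed to
    pass the n_features > 200 & percent_mito < 15 filter), the assigned
    marker ``combination``, and the recomputable QC covariates
    ``n_features`` / ``percent_mito``.  ``var`` flags mitochondrial genes.
    Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    markers = list(config.marker_genes)
    mito = [f"{config.mito_prefix}gene{i}" for i in range(config.n_mito_genes)]
    n_background = config.n_genes - len(markers) - len(mito)
    background = [f"gene{i}" for i in range(n_background)]
    gene_names = markers + mito + background
    marker_idx = {g: i for i, g in enumerate(markers)}
    mito_idx = np.arange(len(markers), len(markers) + len(mito))
    bg_idx = np.arange(len(markers) + len(mito), config.n_genes)

    lattice = _normalize_lattice(
        config.marker_combination_probabilities, config.marker_genes
    )
    combos = list(lattice.keys())
    combo_p = np.array([lattice[c] for c in combos])

    n_fail = int(round(config.low_quality_fraction * config.n_cells))
    n_fail_feat = n_fail // 2
    qc_class = np.array(
        ["fail_features"] * n_fail_feat
        + ["fail_mito"] * (n_fail - n_fail_feat)
        + ["pass"] * (config.n_cells - n_fail)
    )
    rng.shuffle(qc_class)

    rows, cols, vals = [], [], []
    combo_labels, pass_truth = [], []
    for c in range(config.n_cells):
        cls = qc_class[c]
        combo = combos[rng.choice(len(combos), p=combo_p)]
        combo_labels.append(combination_key(combo))
        pass_truth.append(cls == "pass")

        gene_ids: list[int] = []
        counts: list[int] = []
        for g in combo:  # positive marker genes get at least one count
            gene_ids.append(marker_idx[g])
            counts.append(int(1 + rng.poisson(2.0)))

        if cls == "fail_features":
            target_features = int(rng.integers(*config.features_fail) + 1)  # 51..200
            target_features = min(target_features, 200)
            mito_frac = rng.uniform(*config.mito_frac_pass)
        elif cls == "fail_mito":
            target_features = int(rng.integers(config.features_pass[0],
                                               config.features_pass[1] + 1))
            mito_frac = rng.uniform(*config.mito_frac_fail)
        else:
            target_features = int(rng.integers(config.features_pass[0],
                                               config.features_pass[1] + 1))
            mito_frac = rng.uniform(*config.mito_frac_pass)

        n_mito_expr = min(3, len(mito)) if mito else 0
        n_bg = max(target_features - len(gene_ids) - n_mito_expr, 0)
        bg_sel = rng.choice(bg_idx, size=min(n_bg, bg_idx.size), replace=False)
        gene_ids.extend(int(g) for g in bg_sel)
        counts.extend(int(1 + rng.poisson(config.background_mean))
                      for _ in range(bg_sel.size))

        non_mito_total = sum(counts)
        mito_total = int(round(mito_frac / (1.0 - mito_frac) * non_mito_total))
        if n_mito_expr and mito_total > 0:
            split = rng.multinomial(mito_total, np.ones(n_mito_expr) / n_mito_expr)
            for j, m in enumerate(rng.choice(mito_idx, size=n_mito_expr,
                                             replace=False)):
                if split[j] > 0:
                    gene_ids.append(int(m))
                    counts.append(int(split[j]))

        rows.extend([c] * len(gene_ids))
        cols.extend(gene_ids)
        vals.extend(counts)

    x = sp.csr_matrix(
        (vals, (rows, cols)), shape=(config.n_cells, config.n_genes), dtype=np.int64
    )
    adata = ad.AnnData(X=x)
    adata.obs_names = [f"cell{c:05d}" for c in range(config.n_cells)]
    adata.var_names = gene_names
    adata.var["is_mito"] = [g.startswith(config.mito_prefix) for g in gene_names]
    adata.obs["combination"] = combo_labels
    adata.obs["qc_pass_truth"] = np.array(pass_truth)
    n_features = np.asarray((x > 0).sum(axis=1)).ravel()
    totals = np.asarray(x.sum(axis=1)).ravel()
    mito_counts = np.asarray(x[:, mito_idx].sum(axis=1)).ravel() if len(mito) else 0
    adata.obs["n_features"] = n_features
    with np.errstate(invalid="ignore", divide="ignore"):
        adata.obs["percent_mito"] = np.where(
            totals > 0, 100.0 * mito_counts / totals, 0.0
        )
    return adata
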