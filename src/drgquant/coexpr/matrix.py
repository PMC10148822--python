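"""Count-matrix QC filtering, log normalization and threshold co-expression.

Operates on an AnnData of raw integer counts (cells x genes).  The QC rule
retains cells with more than ``min_features`` detected genes and a
mitochondrial percentage strictly below ``max_mito_percent`` (the standard
droplet-QC convention: nFeature > 200 and percent.mt < 15).  Normalized
expression is ln(1 + scale * count / cell_total) with scale 10,000, and a
cell "expresses" a gene when its normalized value strictly exceeds a
threshold (default 0.1); co-expression fractions can be conditioned on a
marker gene (e.g. the fraction of Scn10a+ cells also expressing Piezo2 and
Ntrk1).
"""

from __future__ import annotations

from typing import Sequence

import anndata as ad
import numpy as np
import scipy.sparse as sp

__all__ = [
    "qc_metrics",
    "qc_filter",
    "lognormalize",
    "threshold_coexpression",
]


def _counts(adata: ad.AnnData) -> sp.csr_matrix:
    x = adata.X
    return sp.csr_matrix(x) if not sp.issparse(x) else x.tocsr()


def qc_metrics(adata: ad.AnnData, mito_prefix: str = "mt-") -> ad.AnnData:
    """(Re)compute per-cell QC covariates from the matrix itself.

    Sets ``obs["n_features"]`` (genes with count > 0) and
    ``obs["percent_mito"]`` (100 x mitochondrial counts / total counts;
    mitochondrial genes are those whose name starts with ``mito_prefix``,
    or those flagged in ``var["is_mito"]`` when present).
    """
    x = _counts(adata)
    n_features = np.asarray((x > 0).sum(axis=1)).ravel()
    totals = np.asarray(x.sum(axis=1)).ravel()
    if "is_mito" in adata.var:
        mito_mask = adata.var["is_mito"].to_numpy(dtype=bool)
    else:
        mito_mask = np.asarray(adata.var_names.str.startswith(mito_prefix))
    mito_counts = np.asarray(x[:, mito_mask].sum(axis=1)).ravel()
    adata.obs["n_features"] = n_features
    with np.errstate(invalid="ignore", divide="ignore"):
        adata.obs["percent_mito"] = np.where(
            totals > 0, 100.0 * mito_counts / np.maximum(totals, 1), 0.0
        )
    return adata


def qc_filter(
    adata: ad.AnnData,
    min_features: int = 200,
    max_mito_percent: float = 15.0,
    mito_prefix: str = "mt-",
) -> ad.AnnData:
    """Retain cells with n_features > min_features and percent_mito < max.

    Both inequalities are strict, so a cell with exactly 200 detected genes
    or exactly 15.0% mitochondrial counts is removed.  Covariates are
    recomputed from the matrix (never trusted from ``obs``); the gene set
    and cell order are preserved.  An empty result is permitted.
    """
    qc_metrics(adata, mito_prefix=mito_prefix)
    keep = (adata.obs["n_features"].to_numpy() > min_features) & (
        adata.obs["percent_mito"].to_numpy() < max_mito_percent
    )
    return adata[keep].copy()


def lognormalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Library-size log normalization: ln(1 + scale * count / cell_total).

    Stores the normalized values in ``layers["lognorm"]`` (the raw counts in
    ``X`` are untouched) and returns the same AnnData.  Cells with zero
    total counts are rejected.
    """
    x = _counts(adata).astype(float)
    totals = np.asarray(x.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        raise ValueError("cell(s) with zero total counts; filter first")
    norm = x.multiply(scale / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    adata.layers["lognorm"] = norm
    return adata


def threshold_coexpression(
    adata: ad.AnnData,
    genes: Sequence[str],
    threshold: float = 0.1,
    condition_on: str | None = None,
    use_raw: bool = False,
) -> dict:
    """Count cells expressing every gene in ``genes`` above a threshold.

    A cell expresses a gene when its normalized value (``layers["lognorm"]``,
    computed on demand) is strictly greater than ``threshold``; with
    ``use_raw`` the raw count is thresholded instead (sensitivity analysis).
    With ``condition_on`` the denominator is restricted to cells expressing
    the conditioning gene.

    Returns ``{"n_coexpressing", "n_cells", "fraction"}`` where ``n_cells``
    is the (possibly conditioned) denominator.
    """
    for g in list(genes) + ([condition_on] if condition_on else []):
        if g not in adata.var_names:
            raise KeyError(f"gene {g!r} absent from matrix")
    if use_raw:
        mat = _counts(adata)
    else:
        if "lognorm" not in adata.layers:
            lognormalize(adata)
        mat = sp.csr_matrix(adata.layers["lognorm"])

    def expresses(gene: str) -> np.ndarray:
        col = np.asarray(mat[:, adata.var_names.get_loc(gene)].todense()).ravel()
        return col > threshold

    denom_mask = (
        expresses(condition_on)
        if condition_on is not None
        else np.ones(adata.n_obs, dtype=bool)
    )
    co_mask = denom_mask.copy()
    for g in genes:
        co_mask &= expresses(g)
    n_cells = int(denom_mask.sum())
    n_co = int(co_mask.sum())
    return {
        "n_coexpressing": n_co,
        "n_cells": n_cells,
        "fraction": n_co / n_cells if n_cells else np.nan,
    }
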