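"""Readers and writers for the pipeline's on-disk formats.

Trace tables travel as wide CSV (one row per neuron) with a JSON protocol
sidecar; rendered movies as multi-page TIFF plus a label-image TIFF; marker
tables as tidy CSV; count matrices as a 10x-style MatrixMarket triplet
(matrix.mtx genes x cells, genes.tsv, barcodes.tsv) plus a per-cell
metadata TSV.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
import tifffile

from .imaging import ImagingSession
from .protocol import ImagingProtocol

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_stack",
    "read_stack",
    "write_count_matrix",
    "read_count_matrix",
]


# -- trace tables ------------------------------------------------------------

def write_traces_csv(session: ImagingSession, out_dir: str | Path) -> Path:
    """Write traces.csv (+ protocol.json sidecar); returns the CSV path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        session.traces,
        columns=[f"frame{t}" for t in range(session.traces.shape[1])],
    )
    df.insert(0, "neuron_id", session.neuron_ids)
    df.insert(1, "area_um2", session.areas_um2)
    path = out / "traces.csv"
    df.to_csv(path, index=False)
    session.protocol.to_json(out / "protocol.json")
    return path


def read_traces_csv(
    path: str | Path, protocol: ImagingProtocol | None = None
) -> ImagingSession:
    """Load a trace CSV; the protocol comes from the sidecar if not given."""
    path = Path(path)
    if protocol is None:
        protocol = ImagingProtocol.from_json(path.with_name("protocol.json"))
    df = pd.read_csv(path)
    frame_cols = [c for c in df.columns if c.startswith("frame")]
    return ImagingSession(
        protocol=protocol,
        traces=df[frame_cols].to_numpy(dtype=float),
        neuron_ids=df["neuron_id"].to_numpy(),
        areas_um2=df["area_um2"].to_numpy(dtype=float),
    )


# -- rendered stacks ---------------------------------------------------------

def write_stack(
    stack: np.ndarray, rois: np.ndarray, out_dir: str | Path,
    protocol: ImagingProtocol | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "stack.tif", np.asarray(stack, dtype=np.float32))
    tifffile.imwrite(out / "rois.tif", np.asarray(rois, dtype=np.int32))
    if protocol is not None:
        protocol.to_json(out / "protocol.json")
    return out / "stack.tif"


def read_stack(in_dir: str | Path) -> tuple[np.ndarray, np.ndarray, ImagingProtocol | None]:
    in_dir = Path(in_dir)
    stack = tifffile.imread(in_dir / "stack.tif")
    rois = tifffile.imread(in_dir / "rois.tif")
    proto_path = in_dir / "protocol.json"
    protocol = ImagingProtocol.from_json(proto_path) if proto_path.exists() else None
    return stack, rois, protocol


# -- count matrices ----------------------------------------------------------

def write_count_matrix(adata: ad.AnnData, out_dir: str | Path) -> Path:
    """Write a 10x-style triplet: matrix.mtx (genes x cells), genes.tsv,
    barcodes.tsv, plus metadata.tsv with the per-cell obs columns."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    x = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    sio.mmwrite(out / "matrix.mtx", sp.coo_matrix(x.T), field="integer")
    pd.Series(adata.var_names).to_csv(out / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    if len(adata.obs.columns):
        adata.obs.to_csv(out / "metadata.tsv", sep="\t")
    return out / "matrix.mtx"


def read_count_matrix(in_dir: str | Path) -> ad.AnnData:
    """Round-trip reader for :func:`write_count_matrix` output."""
    in_dir = Path(in_dir)
    x = sio.mmread(in_dir / "matrix.mtx").T.tocsr().astype(np.int64)
    genes = pd.read_csv(in_dir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(in_dir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(X=x)
    adata.var_names = genes.to_list()
    adata.obs_names = barcodes.to_list()
    meta_path = in_dir / "metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        adata.obs = meta.loc[adata.obs_names]
    return adata
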