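"""Labeled sparse count I/O, per-cell QC metrics, cell filtering, normalization.

Datasets live on disk as a 10x-style MatrixMarket triplet — ``matrix.mtx``
(genes as rows, 1-based coordinates), ``features.tsv``, ``barcodes.tsv`` —
plus ``annotation.tsv`` mapping each barcode to its condition
(infected | uninfected) and cell-type label.  In memory they are AnnData
objects (cells x genes, sparse CSR) with the annotation in ``.obs`` and a
``uns["layer"]`` tag of ``raw`` or ``normalized``.

Cell QC follows the removal rule "<=200 detected genes, >=6,000 detected
genes, or >=5% mitochondrial UMIs": the printed boundary values are removed.
Mitochondrial genes are recognized by a configurable, case-insensitive
gene-id prefix (default ``mt:``, the fly convention).

Normalization is standard total-count log-normalization:
``ln(1 + count / cell_total * scale_factor)`` with scale factor 10,000.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

__all__ = [
    "load_dataset",
    "save_dataset",
    "compute_qc_metrics",
    "classify_cells",
    "filter_cells",
    "lognormalize",
]

logger = logging.getLogger(__name__)

MITO_PREFIX = "mt:"
MIN_GENES_EXCLUSIVE = 200
MAX_GENES_EXCLUSIVE = 6000
MAX_MITO_EXCLUSIVE = 5.0


def save_dataset(adata: ad.AnnData, path: str | Path) -> None:
    """Write a dataset as matrix.mtx + features.tsv + barcodes.tsv + annotation.tsv.

    The matrix is written genes x cells with integer values for the raw
    layer; round-trips bit-exactly through :func:`load_dataset`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X.T)
    if adata.uns.get("layer") == "raw":
        X = X.astype(np.int64)
    sio.mmwrite(str(path / "matrix.mtx"), X)
    pd.Series(adata.var_names).to_csv(path / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
    ann = adata.obs[["condition", "cell_type"]].copy()
    ann.index.name = "barcode"
    ann.to_csv(path / "annotation.tsv", sep="\t")


def load_dataset(path: str | Path, layer: str = "raw") -> ad.AnnData:
    """Load a matrix.mtx / features.tsv / barcodes.tsv / annotation.tsv directory.

    Raises ``ValueError`` naming the offending file on a dimension mismatch
    between the triplet files, and listing the barcodes on missing
    annotation rows.
    """
    path = Path(path)
    for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv", "annotation.tsv"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"missing {fname} in {path}")
    M = sp.csr_matrix(sio.mmread(str(path / "matrix.mtx")).T)
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if M.shape[1] != len(features):
        raise ValueError(
            f"matrix.mtx declares {M.shape[1]} genes but features.tsv has "
            f"{len(features)} rows"
        )
    if M.shape[0] != len(barcodes):
        raise ValueError(
            f"matrix.mtx declares {M.shape[0]} cells but barcodes.tsv has "
            f"{len(barcodes)} rows"
        )
    ann = pd.read_csv(path / "annotation.tsv", sep="\t", index_col="barcode")
    missing = [b for b in barcodes if b not in ann.index]
    if missing:
        raise ValueError(f"annotation.tsv is missing barcodes: {missing}")
    bad = set(ann["condition"]) - {"infected", "uninfected"}
    if bad:
        raise ValueError(f"annotation.tsv has unknown condition labels: {sorted(bad)}")
    obs = ann.loc[barcodes, ["condition", "cell_type"]]
    obs.index = pd.Index(barcodes, name="barcode")
    if layer == "raw":
        M = M.astype(np.int64)
    adata = ad.AnnData(X=M, obs=obs, var=pd.DataFrame(index=pd.Index(features, name="gene_id")))
    adata.uns["layer"] = layer
    return adata


def compute_qc_metrics(adata: ad.AnnData, mito_prefix: str = MITO_PREFIX) -> pd.DataFrame:
    """Per-cell QC metrics: detected genes and mitochondrial UMI percentage.

    ``n_genes_detected`` counts genes with count > 0; ``pct_mito`` is the
    percentage of the cell's UMIs coming from genes whose id starts with
    ``mito_prefix`` (case-insensitive).  All-zero cells get (0, 0).
    """
    if adata.uns.get("layer") != "raw":
        raise ValueError("QC metrics are defined on the raw count layer")
    X = sp.csr_matrix(adata.X)
    n_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    is_mito = np.asarray(adata.var_names.str.lower().str.startswith(mito_prefix.lower()))
    mito_totals = (
        np.asarray(X[:, is_mito].sum(axis=1)).ravel().astype(float)
        if is_mito.any()
        else np.zeros(adata.n_obs)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * mito_totals / totals
    pct = np.where(totals > 0, pct, 0.0)
    return pd.DataFrame(
        {"n_genes_detected": n_detected.astype(int), "pct_mito": pct},
        index=adata.obs_names.copy(),
    )


def classify_cells(
    qc: pd.DataFrame,
    min_genes_exclusive: int = MIN_GENES_EXCLUSIVE,
    max_genes_exclusive: int = MAX_GENES_EXCLUSIVE,
    max_mito_exclusive: float = MAX_MITO_EXCLUSIVE,
) -> pd.DataFrame:
    """Attribute each cell to the QC removal rules it violates.

    Returns a boolean frame with columns ``low_genes`` (n <= min),
    ``high_genes`` (n >= max), ``high_mito`` (pct >= max) and ``keep``.
    """
    low = qc["n_genes_detected"] <= min_genes_exclusive
    high = qc["n_genes_detected"] >= max_genes_exclusive
    mito = qc["pct_mito"] >= max_mito_exclusive
    return pd.DataFrame(
        {"low_genes": low, "high_genes": high, "high_mito": mito, "keep": ~(low | high | mito)}
    )


def filter_cells(
    adata: ad.AnnData,
    qc: pd.DataFrame,
    min_genes_exclusive: int = MIN_GENES_EXCLUSIVE,
    max_genes_exclusive: int = MAX_GENES_EXCLUSIVE,
    max_mito_exclusive: float = MAX_MITO_EXCLUSIVE,
) -> ad.AnnData:
    """Remove cells failing the QC rules; boundary values are removed.

    Keeps cells with ``min < n_genes_detected < max`` and
    ``pct_mito < max_mito``; preserves the original barcode order.  Raises
    ``ValueError`` if no cell survives.
    """
    if not qc.index.equals(adata.obs_names):
        qc = qc.loc[adata.obs_names]
    flags = classify_cells(qc, min_genes_exclusive, max_genes_exclusive, max_mito_exclusive)
    keep = flags["keep"].to_numpy()
    if not keep.any():
        raise ValueError(
            "all cells removed by QC filtering; review the thresholds "
            f"(min_genes={min_genes_exclusive}, max_genes={max_genes_exclusive}, "
            f"max_mito={max_mito_exclusive})"
        )
    n_rm = int((~keep).sum())
    if n_rm:
        logger.info(
            "QC removed %d/%d cells (low_genes=%d, high_genes=%d, high_mito=%d)",
            n_rm,
            adata.n_obs,
            int(flags["low_genes"].sum()),
            int(flags["high_genes"].sum()),
            int(flags["high_mito"].sum()),
        )
    out = adata[keep].copy()
    out.uns["layer"] = adata.uns.get("layer", "raw")
    return out


def lognormalize(adata: ad.AnnData, scale_factor: float = 10000.0) -> ad.AnnData:
    """Total-count log-normalization: value <- ln(1 + count/total * scale_factor).

    Depth-invariant within a cell and sparsity-preserving.  Raises on
    zero-total cells (filter first).
    """
    if adata.uns.get("layer") != "raw":
        raise ValueError("lognormalize expects the raw count layer")
    X = sp.csr_matrix(adata.X, dtype=np.float64, copy=True)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        bad = adata.obs_names[totals <= 0].tolist()
        raise ValueError(f"zero-total cells cannot be normalized: {bad}")
    scale = sp.diags(scale_factor / totals)
    X = scale @ X
    X.data = np.log1p(X.data)
    out = adata.copy()
    out.X = X
    out.uns["layer"] = "normalized"
    return out
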