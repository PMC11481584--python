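"""Per-cell-type infected-vs-uninfected differential expression.

For each cell type independently, genes are screened by detection fraction
and fold change (the ``min.pct`` / ``logfc.threshold`` prefilter), tested
with a two-sided Wilcoxon rank-sum test, and BH-adjusted within the cell
type.  Log2 fold changes follow the Seurat-4 convention::

    log2FC = log2( (mean(expm1(norm_infected)) + 1) / (mean(expm1(norm_uninfected)) + 1) )

DEG calling applies the filter cascade |log2FC| >= 0.25, p < 0.05 (raw
Wilcoxon p), and detection in >= 25% of cells in *both* condition
populations.  One-vs-rest cluster markers (positive only, focal detection
>= 0.5) are provided alongside.

The Wilcoxon p-value uses the tie-corrected normal approximation without
continuity correction; an exact enumeration mode over all group assignments
is available for small samples.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEGFilter",
    "wilcoxon_rank_sum",
    "log2_fold_change",
    "bh_adjust",
    "de_contrast_by_celltype",
    "filter_degs",
    "deg_summary",
    "find_cluster_markers",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEGFilter:
    """Thresholds of the DEG filter cascade.

    ``prefilter_min_pct_either`` and ``min_abs_log2fc`` gate which genes are
    tested at all (detection in at least one condition, fold-change screen);
    ``strict_min_pct_both`` and ``max_p`` define the final DEG call.
    ``use_adjusted`` switches the significance rule from raw p to BH q.
    """

    min_abs_log2fc: float = 0.25
    max_p: float = 0.05
    prefilter_min_pct_either: float = 0.25
    strict_min_pct_both: float = 0.25
    use_adjusted: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.max_p <= 1.0:
            raise ValueError("max_p must lie in [0, 1]")
        for name in ("prefilter_min_pct_either", "strict_min_pct_both"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")


PERMISSIVE_FILTER = DEGFilter(min_abs_log2fc=0.0, prefilter_min_pct_either=0.0)


def _ranksum_asymptotic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    W = float(ranks[:n].sum())
    N = n + m
    mu = n * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1.0)))
    if var <= 0:
        return W, 1.0
    z = (W - mu) / np.sqrt(var)
    return W, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _ranksum_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # Exact permutation distribution of the rank-sum statistic on the pooled
    # (tie-averaged) ranks; the tie correction only rescales the statistic by
    # a permutation-invariant constant, so |W - E[W]| is the equivalent
    # two-sided criterion.
    n, m = len(x), len(y)
    N = n + m
    ranks = stats.rankdata(np.concatenate([x, y]))
    W_obs = float(ranks[:n].sum())
    mu = n * (N + 1) / 2.0
    idx = np.array(list(itertools.combinations(range(N), n)), dtype=np.intp)
    W_all = ranks[idx].sum(axis=1)
    eps = 1e-9 * max(1.0, abs(W_obs - mu))
    p = float(np.mean(np.abs(W_all - mu) >= abs(W_obs - mu) - eps))
    return W_obs, p


def wilcoxon_rank_sum(x, y, method: str = "asymptotic") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Parameters
    ----------
    x, y : array-like
        Observations of the two groups (each non-empty).
    method : {"asymptotic", "exact"}
        ``asymptotic``: tie-corrected normal approximation, no continuity
        correction.  ``exact``: full enumeration of all group assignments of
        the pooled sample (small samples only).

    Returns
    -------
    (W, p) : rank-sum of ``x`` over the pooled ranking, and the two-sided
    p-value.  Swapping ``x`` and ``y`` leaves p unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "asymptotic":
        return _ranksum_asymptotic(x, y)
    if method == "exact":
        return _ranksum_exact(x, y)
    raise ValueError(f"unknown method {method!r}")


def ranksum_pvalues_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise tie-corrected asymptotic rank-sum p-values (cells x genes)."""
    if A.shape[1] == 0:
        return np.zeros(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(A, B, axis=0, use_continuity=False, method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isnan(p), 1.0, p)


def log2_fold_change(
    norm_x: np.ndarray, norm_y: np.ndarray, pseudocount: float = 1.0
) -> tuple[float, float, float, float, float]:
    """Seurat-convention fold change between two log-normalized groups.

    Returns ``(log2fc, pct_x, pct_y, mean_x, mean_y)`` where the means are
    arithmetic means of ``expm1`` of the values and
    ``log2fc = log2((mean_x + pseudocount) / (mean_y + pseudocount))``.
    """
    norm_x = np.asarray(norm_x, dtype=float)
    norm_y = np.asarray(norm_y, dtype=float)
    mean_x = float(np.mean(np.expm1(norm_x)))
    mean_y = float(np.mean(np.expm1(norm_y)))
    lfc = float(np.log2((mean_x + pseudocount) / (mean_y + pseudocount)))
    return lfc, float(np.mean(norm_x > 0)), float(np.mean(norm_y > 0)), mean_x, mean_y


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clamped to 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_arrays(norm: ad.AnnData):
    X = sp.csr_matrix(norm.X)
    E = X.copy()
    E.data = np.expm1(E.data)
    D = (X > 0).astype(np.float64)
    return X, E, D


def _pct_mean(E: sp.csr_matrix, D: sp.csr_matrix, mask: np.ndarray):
    n = int(mask.sum())
    pct = np.asarray(D[mask].sum(axis=0)).ravel() / n
    mean = np.asarray(E[mask].sum(axis=0)).ravel() / n
    return pct, mean


def de_contrast_by_celltype(
    norm: ad.AnnData,
    deg_filter: DEGFilter = DEGFilter(),
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Infected-vs-uninfected Wilcoxon DE within each cell type.

    Genes enter testing only if detected in >= ``prefilter_min_pct_either``
    of cells in at least one condition *and* |log2FC| >=
    ``min_abs_log2fc``; BH adjustment runs across the tested genes within
    each cell type.  Cell types missing a condition are skipped with a
    warning.

    Returns one row per tested (gene, cell type) with columns gene_id,
    cell_type, log2fc, p_value, p_adjust, pct_1/pct_2 (detection fraction in
    infected / uninfected), mean_1/mean_2 (mean expm1 expression), n_1/n_2.
    """
    if norm.uns.get("layer") != "normalized":
        raise ValueError("de_contrast_by_celltype expects the normalized layer")
    deg_filter.validate()
    X, E, D = _group_arrays(norm)
    cond = norm.obs["condition"].to_numpy()
    ctype = norm.obs["cell_type"].to_numpy()

    frames = []
    for ct in pd.unique(ctype):
        in_ct = ctype == ct
        m1 = in_ct & (cond == "infected")
        m2 = in_ct & (cond == "uninfected")
        n1, n2 = int(m1.sum()), int(m2.sum())
        if n1 == 0 or n2 == 0:
            logger.warning("cell type %s lacks one condition (n_inf=%d, n_uninf=%d); skipped", ct, n1, n2)
            continue
        pct1, mean1 = _pct_mean(E, D, m1)
        pct2, mean2 = _pct_mean(E, D, m2)
        lfc = np.log2((mean1 + pseudocount) / (mean2 + pseudocount))
        tested = (np.maximum(pct1, pct2) >= deg_filter.prefilter_min_pct_either) & (
            np.abs(lfc) >= deg_filter.min_abs_log2fc
        )
        if not tested.any():
            continue
        A = X[m1][:, tested].toarray()
        B = X[m2][:, tested].toarray()
        p = ranksum_pvalues_matrix(A, B)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": norm.var_names.to_numpy()[tested],
                    "cell_type": ct,
                    "log2fc": lfc[tested],
                    "p_value": p,
                    "p_adjust": bh_adjust(p),
                    "pct_1": pct1[tested],
                    "pct_2": pct2[tested],
                    "mean_1": mean1[tested],
                    "mean_2": mean2[tested],
                    "n_1": n1,
                    "n_2": n2,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "gene_id", "cell_type", "log2fc", "p_value", "p_adjust",
                "pct_1", "pct_2", "mean_1", "mean_2", "n_1", "n_2",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def filter_degs(records: pd.DataFrame, deg_filter: DEGFilter = DEGFilter()) -> pd.DataFrame:
    """Apply the DEG filter cascade to DE records.

    Keeps rows with |log2FC| >= ``min_abs_log2fc``, p below ``max_p``
    (raw p by default, BH q if ``use_adjusted``), and detection >=
    ``strict_min_pct_both`` in both condition populations.
    """
    deg_filter.validate()
    p = records["p_adjust"] if deg_filter.use_adjusted else records["p_value"]
    keep = (
        (records["log2fc"].abs() >= deg_filter.min_abs_log2fc)
        & (p < deg_filter.max_p)
        & (records["pct_1"] >= deg_filter.strict_min_pct_both)
        & (records["pct_2"] >= deg_filter.strict_min_pct_both)
    )
    return records[keep].reset_index(drop=True)


def deg_summary(degs: pd.DataFrame) -> pd.DataFrame:
    """Up/down DEG counts per cell type (up = positive log2FC in infected)."""
    if degs.empty:
        return pd.DataFrame(columns=["cell_type", "n_up", "n_down"])
    out = (
        degs.assign(direction=np.where(degs["log2fc"] > 0, "n_up", "n_down"))
        .groupby(["cell_type", "direction"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["n_up", "n_down"], fill_value=0)
        .reset_index()
    )
    out.columns.name = None
    return out


def find_cluster_markers(
    norm: ad.AnnData,
    labels: pd.Series | np.ndarray | None = None,
    min_pct: float = 0.5,
    min_log2fc: float = 0.25,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One-vs-rest positive marker detection per cell-type cluster.

    A gene is tested for a cluster when detected in >= ``min_pct`` of the
    cluster's cells and its log2FC versus all other cells is >=
    ``min_log2fc`` (positive markers only); BH adjustment per cluster.
    Singleton clusters (or a lone cluster) are skipped with a warning.
    """
    if norm.uns.get("layer") != "normalized":
        raise ValueError("find_cluster_markers expects the normalized layer")
    labels = np.asarray(norm.obs["cell_type"] if labels is None else labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("marker detection requires >= 2 cell types")
    X, E, D = _group_arrays(norm)

    frames = []
    for ct in uniq:
        focal = labels == ct
        rest = ~focal
        if focal.sum() < 2 or rest.sum() < 1:
            logger.warning("cluster %s too small for marker detection; skipped", ct)
            continue
        pct1, mean1 = _pct_mean(E, D, focal)
        pct2, mean2 = _pct_mean(E, D, rest)
        lfc = np.log2((mean1 + pseudocount) / (mean2 + pseudocount))
        tested = (pct1 >= min_pct) & (lfc >= min_log2fc)
        if not tested.any():
            continue
        A = X[focal][:, tested].toarray()
        B = X[rest][:, tested].toarray()
        p = ranksum_pvalues_matrix(A, B)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": norm.var_names.to_numpy()[tested],
                    "cell_type": ct,
                    "log2fc": lfc[tested],
                    "p_value": p,
                    "p_adjust": bh_adjust(p),
                    "pct_1": pct1[tested],
                    "pct_2": pct2[tested],
                    "mean_1": mean1[tested],
                    "mean_2": mean2[tested],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["gene_id", "cell_type", "log2fc", "p_value", "p_adjust",
                     "pct_1", "pct_2", "mean_1", "mean_2"]
        )
    return pd.concat(frames, ignore_index=True)
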