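"""Differential Expression Score (DES) and baseline-coupled regulation analysis.

The DES condenses a gene's effect size and significance in one cell type
into a single signed score::

    DES = sign(log2FC) * log10( (|log2FC| / p.adjust) / r_min )

where ``r_min`` is the minimum of ``|log2FC| / p.adjust`` over the comparison
set (all records scored together by default), so magnitudes are guaranteed
non-negative and the weakest record anchors at 0.  Larger |DES| means a more
intense and more significant expression difference; the sign marks the
direction (negative = downregulated in the infected condition).  An
unnormalized mode (``r_min = 1``) is available.

"Flexible regulation" — effect direction depending on a gene's baseline
expression — is detected per gene as the Spearman correlation, across cell
types, between the DES profile and the per-cell-type average expression in
each condition, with a Fisher-z 95% confidence interval.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_des",
    "des_table",
    "zscore_profile",
    "spearman_with_ci",
    "flexreg_analysis",
]

logger = logging.getLogger(__name__)

P_ADJUST_FLOOR = 1e-300
BASELINE_COLUMNS = {"uninfected_avg": "mean_2", "infected_avg": "mean_1"}


def compute_des(log2fc, p_adjust, r_min: float = 1.0):
    """Signed DES for one or more (log2FC, adjusted p) pairs.

    ``r_min`` is the minimum |log2FC|/p.adjust ratio of the comparison set
    (1.0 for the unnormalized score).  Zero log2FC carries no direction and
    is rejected; p.adjust is floored at 1e-300.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    p_adjust = np.asarray(p_adjust, dtype=float)
    if np.any(log2fc == 0):
        raise ValueError("DES is undefined for log2fc = 0 (no direction)")
    if np.any((p_adjust <= 0) | (p_adjust > 1)):
        p_adjust = np.clip(p_adjust, P_ADJUST_FLOOR, 1.0)
    if not r_min > 0:
        raise ValueError("r_min must be > 0")
    ratio = np.abs(log2fc) / p_adjust
    des = np.sign(log2fc) * np.log10(ratio / r_min)
    return des if des.ndim else float(des)


def des_table(
    records: pd.DataFrame,
    scope: str = "global",
    mode: str = "normalized",
) -> pd.DataFrame:
    """Score DE records with the DES.

    Parameters
    ----------
    records : DataFrame
        DE records carrying ``gene_id``, ``cell_type``, ``log2fc``,
        ``p_adjust``.  Records with log2fc == 0 are dropped (logged).
    scope : {"global", "per_gene"}
        Comparison set over which ``r_min`` is taken in normalized mode.
    mode : {"normalized", "unnormalized"}
        Unnormalized mode fixes ``r_min = 1``.

    Returns a DataFrame with gene_id, cell_type, ratio, des, direction.
    """
    if scope not in ("global", "per_gene"):
        raise ValueError(f"unknown scope {scope!r}")
    if mode not in ("normalized", "unnormalized"):
        raise ValueError(f"unknown mode {mode!r}")
    if records.empty:
        return pd.DataFrame(columns=["gene_id", "cell_type", "ratio", "des", "direction"])
    zero = records["log2fc"] == 0
    if zero.any():
        logger.info("dropping %d zero-log2fc records from DES scoring", int(zero.sum()))
    rec = records.loc[~zero].reset_index(drop=True)
    if rec.empty:
        return pd.DataFrame(columns=["gene_id", "cell_type", "ratio", "des", "direction"])
    padj = np.clip(rec["p_adjust"].to_numpy(dtype=float), P_ADJUST_FLOOR, 1.0)
    ratio = rec["log2fc"].abs().to_numpy() / padj
    if mode == "unnormalized":
        r_min = np.ones(len(rec))
    elif scope == "global":
        r_min = np.full(len(rec), ratio.min())
    else:
        r_min = rec.assign(_r=ratio).groupby("gene_id")["_r"].transform("min").to_numpy()
    des = np.sign(rec["log2fc"].to_numpy()) * np.log10(ratio / r_min)
    return pd.DataFrame(
        {
            "gene_id": rec["gene_id"],
            "cell_type": rec["cell_type"],
            "ratio": ratio,
            "des": des,
            "direction": np.where(rec["log2fc"] > 0, "up", "down"),
        }
    )


def zscore_profile(values) -> np.ndarray:
    """Z-score a per-cell-type average-expression profile (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("z-scoring needs at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("z-score undefined for a constant profile")
    return (v - v.mean()) / sd


def spearman_with_ci(x, y, alpha: float = 0.05, method: str = "asymptotic") -> dict:
    """Spearman correlation with a Fisher-z confidence interval.

    rho is the Pearson correlation of (tie-averaged) ranks.  The p-value
    comes from the t-approximation (``method="asymptotic"``) or from full
    enumeration of all n! rank permutations (``method="exact"``, small n).
    The (1 - alpha) CI uses the Fisher z transform with
    SE = 1.06 / sqrt(n - 3).

    Returns a dict with rho, p_value, ci_low, ci_high, n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("Spearman correlation with CI requires n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if method == "asymptotic":
        p = float(res.pvalue)
    elif method == "exact":
        if math.factorial(n) > 400_000:
            raise ValueError("exact Spearman enumeration is limited to small n")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")
    zcrit = stats.norm.ppf(1 - alpha / 2)
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(rho, -1.0, 1.0))
    half = zcrit * 1.06 / np.sqrt(n - 3)
    ci_low, ci_high = float(np.tanh(z - half)), float(np.tanh(z + half))
    return {"rho": rho, "p_value": p, "ci_low": ci_low, "ci_high": ci_high, "n": n}


def flexreg_analysis(
    des: pd.DataFrame,
    de: pd.DataFrame,
    min_cell_types: int = 4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Spearman correlation of DES against baseline average expression.

    For every gene with DES scores and average-expression values in at least
    ``min_cell_types`` shared cell types, correlates the DES profile with
    the per-cell-type mean expression (mean expm1 of normalized values) in
    the uninfected condition (``baseline = uninfected_avg``) and in the
    infected condition (``infected_avg``).  Genes with too few cell types or
    constant profiles are skipped with a warning.

    Returns one row per (gene, baseline): gene_id, baseline, rho, p_value,
    ci_low, ci_high, n, significant (p < alpha).
    """
    merged = des.merge(
        de[["gene_id", "cell_type", "mean_1", "mean_2"]],
        on=["gene_id", "cell_type"],
        how="inner",
    )
    rows = []
    n_skipped = 0
    for gene, grp in merged.groupby("gene_id", sort=True):
        if len(grp) < min_cell_types:
            n_skipped += 1
            continue
        d = grp["des"].to_numpy()
        for baseline, col in BASELINE_COLUMNS.items():
            xv = grp[col].to_numpy()
            if np.ptp(xv) == 0 or np.ptp(d) == 0:
                n_skipped += 1
                continue
            r = spearman_with_ci(xv, d, alpha=alpha)
            rows.append({"gene_id": gene, "baseline": baseline, **r, "significant": r["p_value"] < alpha})
    if n_skipped:
        logger.warning("flexreg_analysis skipped %d gene/baseline profiles (<%d cell types or constant)", n_skipped, min_cell_types)
    return pd.DataFrame(
        rows,
        columns=["gene_id", "baseline", "rho", "p_value", "ci_low", "ci_high", "n", "significant"],
    )
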