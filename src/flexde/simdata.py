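"""Synthetic two-condition, multi-cell-type UMI count datasets with planted truth.

The generator emulates the structure of an infected-vs-uninfected ovary
single-cell experiment: ~11 cell types of negative-binomially distributed UMI
counts with cell-type-specific baseline means, log-normal library-size
variation, mitochondrial genes flagged by an ``mt:`` name prefix, optional
planted QC-failure cells, and an infection effect model in which a gene's
per-cell-type effect direction and magnitude are negatively coupled to its
baseline expression — the "flexible regulation" structure the downstream
DES/correlation analysis is designed to detect.

Effect model, per affected gene g and cell type c::

    true_log2fc(g, c) = -coupling_beta * z(g, c) + eps,   eps ~ N(0, effect_noise_sd)

where ``z(g, c)`` is the z-score of ``log(baseline_mean(g, c))`` across the
gene's cell types: the gene is pushed down where it is highly expressed at
baseline and up where it is lowly expressed.

Counts are NB draws with mean ``baseline_mean * 2**true_log2fc * depth`` in the
infected condition (``true_log2fc = 0`` when uninfected or unaffected) and
variance ``mu + mu**2 / nb_dispersion``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["SimConfig", "SimTruth", "simulate_dataset", "inject_qc_failures"]

CONDITIONS = ("infected", "uninfected")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic dataset generator.

    Defaults describe the study-scale design used throughout: 2,000 genes,
    11 cell types, 150 cells per cell type per condition, NB size 2
    (variance = mu + mu^2/2), ~exp(N(-0.7, 1)) baseline UMI means, 10% of
    genes carrying a planted infection effect coupled to baseline with slope
    1.5 and residual effect noise of 0.1 log2 units.
    """

    n_genes: int = 2000
    n_cell_types: int = 11
    cells_per_type_per_condition: int = 150
    baseline_logmean_mu: float = -0.7
    baseline_logmean_sd: float = 1.0
    nb_dispersion: float = 2.0
    libsize_sigma: float = 0.25
    frac_mito_genes: float = 0.02
    frac_affected_genes: float = 0.1
    coupling_beta: float = 1.5
    effect_noise_sd: float = 0.1
    n_low_gene_cells: int = 0
    n_high_mito_cells: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_mito_genes", "frac_affected_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "n_genes",
            "cells_per_type_per_condition",
            "n_low_gene_cells",
            "n_high_mito_cells",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_cell_types < 3:
            raise ValueError(
                "n_cell_types must be >= 3: the per-gene z-score of baseline "
                "log-means across cell types is degenerate below 3 cell types"
            )
        if self.baseline_logmean_sd < 0 or self.effect_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be >= 0")


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated dataset.

    Attributes
    ----------
    baseline_mean : DataFrame, genes x cell types
        Uninfected NB mean on the linear scale.
    true_log2fc : DataFrame, genes x cell types
        Planted log2 fold change (infected over uninfected); 0 for
        unaffected genes.
    gene_info : DataFrame indexed by gene_id
        Columns ``affected`` and ``mito`` (bool).
    cell_info : DataFrame indexed by barcode
        Columns ``condition``, ``cell_type``, ``qc_fail_kind``
        (none | low_gene | high_mito).
    config : SimConfig
    """

    baseline_mean: pd.DataFrame
    true_log2fc: pd.DataFrame
    gene_info: pd.DataFrame
    cell_info: pd.DataFrame
    config: SimConfig = field(repr=False)


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise z-score with sample (n-1) sd; constant rows map to 0."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    return np.where(sd > 0, z, 0.0)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    # NB parameterized by size r and success prob p: mean = r(1-p)/p with
    # numpy's convention n=r, p=r/(r+mu); variance = mu + mu^2/r.
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_dataset(config: SimConfig) -> tuple[ad.AnnData, pd.DataFrame, SimTruth]:
    """Simulate a labeled two-condition multi-cell-type raw UMI count matrix.

    Returns
    -------
    adata : AnnData
        Raw counts, cells x genes (sparse CSR); ``obs`` carries ``condition``
        and ``cell_type``; ``uns["layer"] == "raw"``.
    annotation : DataFrame
        Per-barcode ``condition`` and ``cell_type`` (a view of ``adata.obs``).
    truth : SimTruth

    Planted QC-failure cells are *not* added here; see
    :func:`inject_qc_failures`.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))

    G, C = config.n_genes, config.n_cell_types
    n_mito = int(round(config.frac_mito_genes * G))
    mito_idx = rng.choice(G, size=n_mito, replace=False)
    mito = np.zeros(G, dtype=bool)
    mito[mito_idx] = True
    gene_ids = np.array(
        [("mt:" if mito[i] else "") + f"gene{i + 1:05d}" for i in range(G)]
    )

    cell_types = [f"ct{j + 1:02d}" for j in range(C)]
    log_base = rng.normal(config.baseline_logmean_mu, config.baseline_logmean_sd, (G, C))
    baseline = np.exp(log_base)

    n_affected = int(round(config.frac_affected_genes * G))
    affected_idx = rng.choice(G, size=n_affected, replace=False)
    affected = np.zeros(G, dtype=bool)
    affected[affected_idx] = True

    z = _zscore_rows(log_base)
    lfc = np.zeros((G, C))
    if n_affected:
        eps = rng.normal(0.0, config.effect_noise_sd, (n_affected, C))
        lfc[affected_idx] = -config.coupling_beta * z[affected_idx] + eps

    n_per = config.cells_per_type_per_condition
    blocks, barcodes, conds, types = [], [], [], []
    # Log-normal depth factors with E[depth] = 1 so the marginal mean stays
    # baseline * 2^lfc on the ratio scale.
    depth_mu = -0.5 * config.libsize_sigma**2
    for j, ct in enumerate(cell_types):
        for cond in CONDITIONS:
            depth = rng.lognormal(depth_mu, config.libsize_sigma, n_per)
            mu_gene = baseline[:, j] * (2.0 ** lfc[:, j] if cond == "infected" else 1.0)
            mean = mu_gene[:, None] * depth[None, :]
            blocks.append(_nb_draw(rng, mean, config.nb_dispersion))
            barcodes.extend(f"{cond}_{ct}_{i + 1:04d}" for i in range(n_per))
            conds.extend([cond] * n_per)
            types.extend([ct] * n_per)

    counts = np.concatenate(blocks, axis=1) if blocks else np.zeros((G, 0), dtype=np.int64)
    obs = pd.DataFrame(
        {"condition": conds, "cell_type": types},
        index=pd.Index(barcodes, name="barcode"),
    )
    adata = ad.AnnData(
        X=sp.csr_matrix(counts.T.astype(np.int64)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )
    adata.uns["layer"] = "raw"

    truth = SimTruth(
        baseline_mean=pd.DataFrame(baseline, index=gene_ids, columns=cell_types),
        true_log2fc=pd.DataFrame(lfc, index=gene_ids, columns=cell_types),
        gene_info=pd.DataFrame(
            {"affected": affected, "mito": mito}, index=pd.Index(gene_ids, name="gene_id")
        ),
        cell_info=obs.assign(qc_fail_kind="none"),
        config=config,
    )
    return adata, adata.obs[["condition", "cell_type"]].copy(), truth


def inject_qc_failures(
    adata: ad.AnnData, truth: SimTruth, config: SimConfig | None = None
) -> tuple[ad.AnnData, SimTruth]:
    """Append planted QC-failure cells to a raw count matrix.

    Adds ``n_low_gene_cells`` cells detecting <= 200 genes and
    ``n_high_mito_cells`` cells whose mitochondrial UMI share is >= 5%,
    recording ``qc_fail_kind`` in the returned truth.  Raises ``ValueError``
    if high-mito cells are requested but the matrix carries no ``mt:`` genes.
    """
    if config is None:
        config = truth.config
    if adata.uns.get("layer") != "raw":
        raise ValueError("inject_qc_failures requires the raw count layer")
    n_low, n_high = config.n_low_gene_cells, config.n_high_mito_cells
    if n_low == 0 and n_high == 0:
        return adata, truth

    gene_ids = adata.var_names.to_numpy()
    mito = np.array([g.lower().startswith("mt:") for g in gene_ids])
    if n_high > 0 and not mito.any():
        raise ValueError(
            "n_high_mito_cells > 0 but the matrix has no mito-flagged ('mt:') genes"
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    G = adata.n_vars
    cell_types = truth.baseline_mean.columns.to_numpy()
    baseline = truth.baseline_mean.to_numpy()

    rows, barcodes, conds, types, kinds = [], [], [], [], []

    for i in range(n_low):
        # sparse low-complexity cell: single UMIs in <=150 genes
        k = min(150, G)
        genes = rng.choice(G, size=k, replace=False)
        row = np.zeros(G, dtype=np.int64)
        row[genes] = 1
        rows.append(row)
        barcodes.append(f"lowgene_{i + 1:04d}")
        j = int(rng.integers(len(cell_types)))
        conds.append(CONDITIONS[int(rng.integers(2))])
        types.append(cell_types[j])
        kinds.append("low_gene")

    for i in range(n_high):
        j = int(rng.integers(len(cell_types)))
        row = _nb_draw(rng, baseline[:, j], config.nb_dispersion).astype(np.int64)
        non_mito_total = int(row[~mito].sum())
        # push the mito share to ~10% of UMIs (comfortably past the 5% filter)
        needed = max(1, int(np.ceil(non_mito_total / 9.0)))
        mito_idx = np.flatnonzero(mito)
        per = needed // len(mito_idx)
        row[mito_idx] += per
        row[mito_idx[: needed - per * len(mito_idx)]] += 1
        rows.append(row)
        barcodes.append(f"highmito_{i + 1:04d}")
        conds.append(CONDITIONS[int(rng.integers(2))])
        types.append(cell_types[j])
        kinds.append("high_mito")

    extra_obs = pd.DataFrame(
        {"condition": conds, "cell_type": types},
        index=pd.Index(barcodes, name="barcode"),
    )
    extra = ad.AnnData(
        X=sp.csr_matrix(np.vstack(rows)),
        obs=extra_obs,
        var=pd.DataFrame(index=adata.var_names),
    )
    out = ad.concat([adata, extra], join="outer", merge="same")
    out.var_names = adata.var_names
    out.uns["layer"] = "raw"
    out.X = sp.csr_matrix(out.X)

    cell_info = pd.concat([truth.cell_info, extra_obs.assign(qc_fail_kind=kinds)])
    new_truth = SimTruth(
        baseline_mean=truth.baseline_mean,
        true_log2fc=truth.true_log2fc,
        gene_info=truth.gene_info,
        cell_info=cell_info,
        config=config,
    )
    return out, new_truth


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
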