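import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

from flexde import SimConfig, simulate_dataset, inject_qc_failures, lognormalize

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def make_adata(counts, gene_ids, barcodes, condition=None, cell_type=None, layer="raw"):
    """Build a raw AnnData from a dense genes x cells array."""
    counts = np.asarray(counts)
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    obs["condition"] = condition if condition is not None else "uninfected"
    obs["cell_type"] = cell_type if cell_type is not None else "ct01"
    adata = ad.AnnData(
        X=sp.csr_matrix(counts.T.astype(np.int64 if layer == "raw" else float)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )
    adata.uns["layer"] = layer
    return adata


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_genes=1000,
        n_cell_types=6,
        cells_per_type_per_condition=60,
        n_low_gene_cells=4,
        n_high_mito_cells=3,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Simulated dataset with planted QC failures, plus its truth."""
    adata, annotation, truth = simulate_dataset(small_config)
    adata, truth = inject_qc_failures(adata, truth, small_config)
    return adata, truth


@pytest.fixture(scope="session")
def small_norm(small_dataset):
    """Normalized expression of the small dataset's clean cells."""
    adata, truth = small_dataset
    clean = truth.cell_info["qc_fail_kind"] == "none"
    sub = adata[clean.to_numpy()].copy()
    sub.uns["layer"] = "raw"
    return lognormalize(sub)
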