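"""Shared fixtures: small simulated datasets generated once per session."""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from betacohort.simulate import SimulationConfig, generate_cohorts


@pytest.fixture(scope="session")
def sim_small():
    """Two-cohort (tenx + smartseq2) dataset with planted DE and hub signal."""
    cfg = SimulationConfig(
        n_cohorts=2,
        technology_per_cohort=["tenx", "smartseq2"],
        donors_per_cohort_per_group=4,
        cells_per_donor=(60, 100),
        n_genes=1000,
        n_marker_genes_per_celltype=3,
        n_robust_de_genes=8,
        n_private_de_genes_per_cohort=8,
        n_hub_correlated_genes=5,
        seed=42,
    )
    return generate_cohorts(cfg)


@pytest.fixture()
def tiny_adata():
    """Hand-built 3-cell x 4-gene dataset with full metadata."""
    X = sparse.csr_matrix(
        np.array([[5, 0, 2, 1], [0, 3, 0, 0], [1, 1, 1, 1]], dtype=np.int64)
    )
    obs = pd.DataFrame(
        {
            "donor_id": ["d1", "d1", "d2"],
            "cohort_id": ["c1", "c1", "c1"],
            "technology": ["tenx", "tenx", "tenx"],
            "disease": ["ND", "ND", "T2D"],
        },
        index=pd.Index(["cellA", "cellB", "cellC"], name="cell_id"),
    )
    var = pd.DataFrame(index=pd.Index(["INS", "GCG", "MT-1", "G1"], name="gene_id"))
    return ad.AnnData(X=X, obs=obs, var=var)
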