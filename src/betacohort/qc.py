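"""Cell-level quality control, ln(TPM+1) normalization, marker annotation.

QC keeps cells that (i) express strictly more than ``min_genes`` genes,
(ii) have a mitochondrial count fraction strictly below a technology-specific
cutoff (droplet 10%, plate 20%), and (iii) are not in the top read-depth
percentile of their cohort.  The depth percentile is computed per cohort,
after the gene/mito filters, because cohorts of different technologies differ
in depth by an order of magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    min_genes: int = 500
    mito_max_tenx: float = 0.10
    mito_max_smartseq2: float = 0.20
    top_read_quantile: float = 0.01
    mito_gene_prefix: str = "MT-"

    def validate(self) -> None:
        if not 0.0 < self.top_read_quantile < 1.0:
            raise ValueError("top_read_quantile must lie in (0, 1)")
        for name in ("mito_max_tenx", "mito_max_smartseq2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def cell_qc_metrics(adata: ad.AnnData, mito_gene_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell n_genes_detected, total_counts and mito_fraction."""
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    X = X.tocsr()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = adata.var_names.str.startswith(mito_gene_prefix)
    mito_counts = np.asarray(X[:, np.asarray(mito_mask)].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    return pd.DataFrame(
        {
            "n_genes_detected": n_genes.astype(int),
            "total_counts": totals.astype(np.int64),
            "mito_fraction": mito_frac,
        },
        index=adata.obs_names,
    )


def filter_cells(
    adata: ad.AnnData,
    config: QCConfig | None = None,
    apply_top_quantile: bool = True,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Apply the three QC filters; return (filtered copy, per-cell QC table).

    The QC table covers *every* input cell with the three metric columns,
    one boolean per filter and the combined ``qc_pass``.  Strict inequalities
    throughout: a cell with exactly ``min_genes`` detected genes or exactly
    the mito cutoff is removed.  The top-quantile depth rule is evaluated
    within each cohort among cells that survived the first two filters; set
    ``apply_top_quantile=False`` when re-filtering already-filtered data.
    """
    config = config or QCConfig()
    config.validate()
    qc = cell_qc_metrics(adata, config.mito_gene_prefix)
    obs = adata.obs

    pass_genes = qc["n_genes_detected"].to_numpy() > config.min_genes
    mito_cut = np.where(
        obs["technology"].to_numpy() == "smartseq2",
        config.mito_max_smartseq2,
        config.mito_max_tenx,
    )
    pass_mito = qc["mito_fraction"].to_numpy() < mito_cut

    pass_depth = np.ones(adata.n_obs, dtype=bool)
    if apply_top_quantile:
        survivors = pass_genes & pass_mito
        for cohort in pd.unique(obs["cohort_id"]):
            in_cohort = (obs["cohort_id"] == cohort).to_numpy()
            sel = in_cohort & survivors
            if not sel.any():
                continue
            cutoff = np.quantile(
                qc["total_counts"].to_numpy()[sel], 1.0 - config.top_read_quantile
            )
            pass_depth[in_cohort] = qc["total_counts"].to_numpy()[in_cohort] < cutoff

    qc["pass_min_genes"] = pass_genes
    qc["pass_mito"] = pass_mito
    qc["pass_depth"] = pass_depth
    qc["qc_pass"] = pass_genes & pass_mito & pass_depth

    kept = qc["qc_pass"].to_numpy()
    if not kept.any():
        logger.warning("QC removed every cell")
    filtered = adata[kept].copy()
    filtered.obs["n_genes_detected"] = qc.loc[kept, "n_genes_detected"].to_numpy()
    filtered.obs["total_counts"] = qc.loc[kept, "total_counts"].to_numpy()
    filtered.obs["mito_fraction"] = qc.loc[kept, "mito_fraction"].to_numpy()
    return filtered, qc


def ln_tpm1(
    counts: sparse.spmatrix | np.ndarray,
    gene_lengths_kb: np.ndarray | None = None,
) -> sparse.csr_matrix:
    """ln(TPM + 1) per cell.

    Without gene lengths all genes are treated as equal length, i.e. TPM
    coincides with CPM — appropriate for droplet (UMI) data.  For full-length
    plate protocols pass per-gene lengths in kilobases.  Cells with zero total
    counts come out as all-zero rows (with a logged warning).
    """
    X = counts.tocsr().astype(np.float64) if sparse.issparse(counts) else sparse.csr_matrix(
        np.asarray(counts, dtype=np.float64)
    )
    if (X.data < 0).any():
        raise ValueError("counts must be non-negative")
    if gene_lengths_kb is not None:
        lengths = np.asarray(gene_lengths_kb, dtype=np.float64)
        if lengths.shape[0] != X.shape[1] or (lengths <= 0).any():
            raise ValueError("gene_lengths_kb must be positive, one per gene")
        X = X.multiply(1.0 / lengths).tocsr()
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        logger.warning("%d cell(s) with zero total counts normalized to all-zero", zero.sum())
    scale = np.divide(1e6, totals, out=np.zeros_like(totals), where=~zero)
    X = sparse.diags(scale) @ X
    X.data = np.log1p(X.data)
    return X.tocsr()


def normalize(adata: ad.AnnData, gene_lengths_kb: np.ndarray | None = None) -> ad.AnnData:
    """Store ln(TPM+1) in ``adata.layers['ln_tpm1']`` (in place, returns adata)."""
    adata.layers["ln_tpm1"] = ln_tpm1(adata.X, gene_lengths_kb)
    return adata


def assign_cell_types(
    expr: sparse.spmatrix | np.ndarray,
    gene_ids,
    markers: dict[str, list[str]],
) -> np.ndarray:
    """Label each cell by the cell type with the highest mean marker expression.

    ``expr`` is normalized expression (cells x genes).  Marker genes missing
    from ``gene_ids`` are dropped with a warning; a cell whose best score is 0
    or shared by several types is labelled ``"unassigned"``.
    """
    if not markers:
        raise ValueError("marker map is empty")
    gene_index = pd.Index(gene_ids)
    X = expr.tocsc() if sparse.issparse(expr) else np.asarray(expr)
    types = sorted(markers)
    scores = np.zeros((X.shape[0] if hasattr(X, "shape") else len(X), len(types)))
    for j, ct in enumerate(types):
        present = [g for g in markers[ct] if g in gene_index]
        dropped = set(markers[ct]) - set(present)
        if dropped:
            logger.warning("markers for %s not in matrix: %s", ct, sorted(dropped))
        if not present:
            continue
        cols = gene_index.get_indexer(present)
        sub = X[:, cols]
        scores[:, j] = (
            np.asarray(sub.mean(axis=1)).ravel() if sparse.issparse(sub) else sub.mean(axis=1)
        )
    best = scores.max(axis=1)
    argbest = scores.argmax(axis=1)
    ties = (scores == best[:, None]).sum(axis=1) > 1
    labels = np.asarray(types, dtype=object)[argbest]
    labels[(best <= 0) | ties] = "unassigned"
    return labels


#: Default marker map matching the generator's canonical islet markers.
DEFAULT_MARKERS = {
    "alpha": ["GCG"],
    "beta": ["INS"],
    "delta": ["SST"],
    "gamma": ["PPY"],
    "other": ["REG1A", "CFTR", "PDGFRB", "CLEC14A", "CCL3"],
}
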