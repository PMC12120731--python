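"""MatrixMarket + TSV reading and writing for cell-by-gene count matrices.

On disk the matrix follows the CellRanger convention (genes as MTX rows,
cells as columns) with `genes.tsv`, `barcodes.tsv` and a `cell_metadata.tsv`
carrying donor / cohort / technology / disease per cell.  Gzipped variants of
every file are read transparently.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

VALID_TECHNOLOGIES = {"tenx", "smartseq2"}
VALID_DISEASES = {"ND", "PreT2D", "T2D"}

METADATA_COLUMNS = ["cell_id", "donor_id", "cohort_id", "technology", "disease"]


class MatrixFormatError(ValueError):
    """A file on disk is inconsistent with its companions."""


def _resolve(outdir_or_path: str | Path, default_name: str) -> Path:
    p = Path(outdir_or_path)
    if p.is_dir():
        return p / default_name
    return p


def write_matrix(adata: ad.AnnData, outdir: str | Path) -> dict[str, Path]:
    """Write counts as matrix.mtx (genes x cells) + genes/barcodes/metadata TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "genes": outdir / "genes.tsv",
        "barcodes": outdir / "barcodes.tsv",
        "metadata": outdir / "cell_metadata.tsv",
    }
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    scio.mmwrite(str(paths["matrix"]), X.T.tocoo(), field="integer")
    pd.Series(adata.var_names).to_csv(paths["genes"], sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    meta = adata.obs.reset_index(names="cell_id")
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    return paths


def read_matrix(
    matrix: str | Path,
    genes: str | Path | None = None,
    barcodes: str | Path | None = None,
    metadata: str | Path | None = None,
) -> ad.AnnData:
    """Read an MTX triplet + metadata TSV into an AnnData (cells x genes).

    ``matrix`` may be a directory holding the four conventionally named files.
    Raises :class:`MatrixFormatError` naming the offending file when
    dimensions disagree, and ``ValueError`` on unknown technology or disease
    strings.
    """
    mpath = Path(matrix)
    if mpath.is_dir():
        genes = genes or _first_existing(mpath, "genes.tsv")
        barcodes = barcodes or _first_existing(mpath, "barcodes.tsv")
        if metadata is None:
            try:
                metadata = _first_existing(mpath, "cell_metadata.tsv")
            except FileNotFoundError:
                metadata = None  # bare MTX triplet without per-cell metadata
        mpath = _first_existing(mpath, "matrix.mtx")
    if genes is None or barcodes is None:
        raise ValueError("genes and barcodes paths are required")

    M = scio.mmread(str(mpath))  # genes x cells on disk
    gene_ids = pd.read_csv(genes, sep="\t", header=None).iloc[:, 0].astype(str)
    cell_ids = pd.read_csv(barcodes, sep="\t", header=None).iloc[:, 0].astype(str)
    if M.shape[0] != len(gene_ids):
        raise MatrixFormatError(
            f"{genes}: {len(gene_ids)} gene ids but matrix has {M.shape[0]} rows"
        )
    if M.shape[1] != len(cell_ids):
        raise MatrixFormatError(
            f"{barcodes}: {len(cell_ids)} cell ids but matrix has {M.shape[1]} columns"
        )
    if gene_ids.duplicated().any():
        raise MatrixFormatError(f"{genes}: duplicate gene ids")
    if cell_ids.duplicated().any():
        raise MatrixFormatError(f"{barcodes}: duplicate cell ids")

    X = sparse.csr_matrix(M.T)
    if (X.data < 0).any():
        raise MatrixFormatError(f"{mpath}: negative counts")

    obs = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t")
        missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
        if missing:
            raise MatrixFormatError(f"{metadata}: missing columns {missing}")
        if len(meta) != len(cell_ids):
            raise MatrixFormatError(
                f"{metadata}: {len(meta)} rows for {len(cell_ids)} cells"
            )
        meta = meta.set_index("cell_id")
        if not meta.index.equals(obs.index):
            if set(meta.index) != set(obs.index):
                raise MatrixFormatError(f"{metadata}: cell ids do not match barcodes")
            meta = meta.loc[obs.index]
        bad_tech = set(meta["technology"]) - VALID_TECHNOLOGIES
        if bad_tech:
            raise ValueError(f"unknown technology values: {sorted(bad_tech)}")
        bad_dis = set(meta["disease"]) - VALID_DISEASES
        if bad_dis:
            raise ValueError(f"unknown disease values: {sorted(bad_dis)}")
        obs = meta

    var = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    return ad.AnnData(X=X, obs=obs, var=var)


def _first_existing(directory: Path, name: str) -> Path:
    for candidate in (directory / name, directory / (name + ".gz")):
        if candidate.exists():
            return candidate
    raise FileNotFoundError(directory / name)


def roundtrip_equal(a: ad.AnnData, b: ad.AnnData) -> bool:
    """True when two AnnData objects hold identical counts and identifiers."""
    if list(a.obs_names) != list(b.obs_names) or list(a.var_names) != list(b.var_names):
        return False
    Xa = sparse.csr_matrix(a.X)
    Xb = sparse.csr_matrix(b.X)
    return (Xa != Xb).nnz == 0 and np.array_equal(Xa.toarray(), Xb.toarray())
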