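"""Synthetic multi-cohort islet single-cell data with known ground truth.

Emulates the statistical structure of an integrated human islet atlas built
from several published cohorts: two library technologies (droplet "tenx" and
plate "smartseq2") with very different depths, donors nested in disease groups
(ND / PreT2D / T2D), negative-binomial counts, marker-defined cell types,
disease effects that replicate across every cohort (robust DE genes) next to
cohort-private ones, a donor-level latent factor that couples a hub gene
(named ZNT8, the beta-cell zinc transporter) to partner genes, donors whose
annotated disease label contradicts their expression (label-swapped
"outliers"), mitochondrial content, and rare ultra-deep "jackpot" cells.

Every gene, donor and cell that carries planted signal is reported in a
:class:`GroundTruth` object so that downstream stages (QC, donor
cross-validation, differential expression, correlation, subpopulation
composition) can be tested as parameter-recovery problems.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

CELL_TYPES = ("alpha", "beta", "delta", "gamma", "other")

#: Canonical islet marker genes per cell type; extra markers beyond these
#: lists get synthetic names like ALPHA-M6.
MARKER_NAMES = {
    "alpha": ["GCG", "TTR", "IRX2", "ARX", "LOXL4"],
    "beta": ["INS", "IAPP", "DLK1", "MAFA", "NKX6-1"],
    "delta": ["SST", "RBP4", "HHEX", "LEPR", "BCHE"],
    "gamma": ["PPY", "AQP3", "ID2", "ETV1", "SLITRK6"],
    "other": ["REG1A", "CFTR", "PDGFRB", "CLEC14A", "CCL3"],
}

HUB_GENE = "ZNT8"
HUB_PARTNER_NAMES = ["G3BP1", "EIF2AK1", "PRKRA"]

_TENX_BASE_DEPTH = 3000.0
_SMARTSEQ2_DEPTH_FACTOR = 10.0  # plate libraries are ~10x deeper
_MARKER_UPLIFT = 20.0
_HUB_BASE_LOG_RATE = math.log(10.0)
_COHORT_BIAS_SD = 0.3
_DEPTH_LOGNORMAL_SD = 0.3
_JACKPOT_DEPTH_FACTOR = 20.0
_HIGH_MITO_BOOST = 8.0


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic multi-cohort experiment.

    Defaults describe six cohorts of mixed technology with ten donors per
    disease group each, a few thousand genes, and planted robust /
    cohort-private differential genes plus a correlated hub module.
    """

    n_cohorts: int = 6
    technology_per_cohort: list[str] | None = None
    donors_per_cohort_per_group: int = 10
    disease_groups: tuple[str, ...] = ("ND", "T2D")
    cells_per_donor: tuple[int, int] = (150, 250)
    n_genes: int = 2000
    n_marker_genes_per_celltype: int = 5
    celltype_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "alpha": 0.30,
            "beta": 0.45,
            "delta": 0.10,
            "gamma": 0.10,
            "other": 0.05,
        }
    )
    n_robust_de_genes: int = 20
    robust_log2fc: float = 1.0
    n_private_de_genes_per_cohort: int = 30
    n_hub_correlated_genes: int = 10
    hub_correlation: float = 0.9
    hub_latent_sd: float = 0.4
    hub_donor_sd: float = 0.25
    background_donor_sd: float = 0.02
    hub_t2d_log2fc: float = 0.0
    t2d_donor_noise_scale: float = 1.0
    hba1c_expression_corr: float = 0.8
    frac_outlier_donors: float = 0.0
    nb_dispersion: float = 2.0
    mito_gene_fraction: float = 0.02
    frac_jackpot_cells: float = 0.005
    frac_high_mito_cells: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.technology_per_cohort is None:
            # mostly droplet cohorts with a plate cohort every third dataset
            self.technology_per_cohort = [
                "smartseq2" if i % 3 == 2 else "tenx" for i in range(self.n_cohorts)
            ]

    def validate(self) -> None:
        if self.n_cohorts < 1:
            raise SimulationError("n_cohorts must be >= 1")
        if len(self.technology_per_cohort) != self.n_cohorts:
            raise SimulationError("technology_per_cohort length must equal n_cohorts")
        bad = set(self.technology_per_cohort) - {"tenx", "smartseq2"}
        if bad:
            raise SimulationError(f"unknown technologies: {sorted(bad)}")
        unknown_groups = set(self.disease_groups) - {"ND", "PreT2D", "T2D"}
        if unknown_groups:
            raise SimulationError(f"unknown disease groups: {sorted(unknown_groups)}")
        if self.cells_per_donor[0] < 1 or self.cells_per_donor[1] < self.cells_per_donor[0]:
            raise SimulationError("cells_per_donor must be a range with lower bound >= 1")
        props = self.celltype_proportions
        if set(props) != set(CELL_TYPES):
            raise SimulationError(f"celltype_proportions must cover {CELL_TYPES}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise SimulationError("celltype_proportions must sum to 1 within 1e-9")
        if not 0.0 <= self.frac_outlier_donors <= 1.0:
            raise SimulationError("frac_outlier_donors must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be positive")
        if not 0.0 <= self.hub_correlation < 1.0:
            raise SimulationError("hub_correlation must lie in [0, 1)")
        n_named = (
            self.n_marker_genes_per_celltype * len(CELL_TYPES)
            + 1  # hub
            + self.n_hub_correlated_genes
            + round(self.mito_gene_fraction * self.n_genes)
        )
        n_planted = (
            self.n_robust_de_genes
            + self.n_cohorts * self.n_private_de_genes_per_cohort
        )
        if n_named + n_planted > self.n_genes:
            raise SimulationError(
                "gene classes (markers, hub module, mito, robust and private DE) "
                f"need {n_named + n_planted} genes but n_genes={self.n_genes}"
            )


@dataclass
class GroundTruth:
    """Everything planted into a simulated dataset.

    ``robust_de`` / ``private_de`` map gene id to the sign of its T2D effect
    (+1 up in T2D).  ``hub_correlation`` is the construction value of the
    donor-level log-expression Pearson correlation between any two genes of
    the hub module.  ``outlier_donors`` maps each label-swapped donor to its
    true (pre-swap) disease group.  ``donors`` is one row per donor with both
    annotated and true labels plus covariates (HbA1c in %).
    """

    robust_de: dict[str, int]
    private_de: dict[str, dict[str, int]]
    hub_gene: str
    hub_partners: list[str]
    hub_correlation: float
    outlier_donors: dict[str, str]
    donors: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        payload = {
            "robust_de": self.robust_de,
            "private_de": self.private_de,
            "hub_gene": self.hub_gene,
            "hub_partners": self.hub_partners,
            "hub_correlation": self.hub_correlation,
            "outlier_donors": self.outlier_donors,
            "donors": self.donors.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _build_gene_universe(cfg: SimulationConfig, rng: np.random.Generator):
    """Assign names, baseline log-rates and disjoint signal classes to genes."""
    n = cfg.n_genes
    names: list[str] = []
    marker_idx: dict[str, np.ndarray] = {}
    for ct in CELL_TYPES:
        canon = MARKER_NAMES[ct]
        ids = [
            canon[k] if k < len(canon) else f"{ct.upper()}-M{k + 1}"
            for k in range(cfg.n_marker_genes_per_celltype)
        ]
        marker_idx[ct] = np.arange(len(names), len(names) + len(ids))
        names.extend(ids)

    hub_idx = len(names)
    names.append(HUB_GENE)
    partner_ids = [
        HUB_PARTNER_NAMES[k] if k < len(HUB_PARTNER_NAMES) else f"HUBP{k + 1}"
        for k in range(cfg.n_hub_correlated_genes)
    ]
    partner_idx = np.arange(len(names), len(names) + len(partner_ids))
    names.extend(partner_ids)

    n_mito = round(cfg.mito_gene_fraction * n)
    mito_idx = np.arange(len(names), len(names) + n_mito)
    names.extend(f"MT-{k + 1}" for k in range(n_mito))

    n_filler = n - len(names)
    filler_idx = np.arange(len(names), n)
    names.extend(f"G{k + 1:05d}" for k in range(n_filler))

    log_rate = np.empty(n)
    log_rate[filler_idx] = rng.normal(0.0, 1.0, n_filler)
    for ct in CELL_TYPES:
        log_rate[marker_idx[ct]] = rng.normal(0.0, 0.3, len(marker_idx[ct]))
    log_rate[hub_idx] = rng.normal(_HUB_BASE_LOG_RATE, 0.1)
    log_rate[partner_idx] = rng.normal(_HUB_BASE_LOG_RATE, 0.2, len(partner_idx))
    # mito genes sized so the aggregate mito fraction lands near a few percent
    log_rate[mito_idx] = rng.normal(1.2, 0.3, n_mito)

    # DE genes are drawn from decently expressed filler genes so the planted
    # effects are detectable at single-cell depth
    eligible = filler_idx[log_rate[filler_idx] > np.median(log_rate[filler_idx])]
    n_need = cfg.n_robust_de_genes + cfg.n_cohorts * cfg.n_private_de_genes_per_cohort
    if n_need > len(eligible):
        eligible = filler_idx  # fall back to the whole filler pool
    if n_need > len(eligible):
        raise SimulationError("not enough genes left to plant DE effects")
    chosen = rng.choice(eligible, size=n_need, replace=False)
    robust_idx = chosen[: cfg.n_robust_de_genes]
    private_idx = {
        ci: chosen[
            cfg.n_robust_de_genes + ci * cfg.n_private_de_genes_per_cohort:
            cfg.n_robust_de_genes + (ci + 1) * cfg.n_private_de_genes_per_cohort
        ]
        for ci in range(cfg.n_cohorts)
    }
    robust_sign = rng.choice([-1, 1], size=cfg.n_robust_de_genes)
    private_sign = {
        ci: rng.choice([-1, 1], size=cfg.n_private_de_genes_per_cohort)
        for ci in range(cfg.n_cohorts)
    }
    return (
        np.asarray(names, dtype=object),
        log_rate,
        marker_idx,
        hub_idx,
        partner_idx,
        mito_idx,
        robust_idx,
        robust_sign,
        private_idx,
        private_sign,
    )


def _disease_effect_scale(group: str) -> float:
    """PreT2D donors carry half of the T2D effect on the log2 scale."""
    return {"ND": 0.0, "PreT2D": 0.5, "T2D": 1.0}[group]


def generate_cohorts(cfg: SimulationConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate a multi-cohort dataset.

    Returns an :class:`anndata.AnnData` with raw negative-binomial counts in
    ``.X`` (cells x genes, CSR) and per-cell metadata in ``.obs`` (donor_id,
    cohort_id, technology, disease as *annotated*, celltype_true, hba1c),
    together with the :class:`GroundTruth`.

    The same config (including seed) always yields byte-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    (
        names,
        log_rate,
        marker_idx,
        hub_idx,
        partner_idx,
        mito_idx,
        robust_idx,
        robust_sign,
        private_idx,
        private_sign,
    ) = _build_gene_universe(cfg, rng)
    n_genes = cfg.n_genes
    hub_module = np.concatenate([[hub_idx], partner_idx]).astype(int)

    # loading of the shared donor latent factor chosen so that the donor-level
    # log-expression correlation between any two hub-module genes equals
    # hub_correlation:  rho = w^2 sz^2 / (w^2 sz^2 + s^2)
    s = cfg.hub_donor_sd
    if cfg.hub_correlation > 0 and len(partner_idx) > 0 and cfg.hub_latent_sd > 0:
        w = (s / cfg.hub_latent_sd) * math.sqrt(
            cfg.hub_correlation / (1.0 - cfg.hub_correlation)
        )
        true_rho = cfg.hub_correlation
    else:
        w = 0.0
        true_rho = 0.0

    cohort_ids = [f"cohort{i + 1}" for i in range(cfg.n_cohorts)]
    cohort_bias = rng.normal(0.0, _COHORT_BIAS_SD, size=(cfg.n_cohorts, n_genes))

    ln2 = math.log(2.0)
    props = np.array([cfg.celltype_proportions[ct] for ct in CELL_TYPES])

    donor_rows = []
    blocks: list[sparse.csr_matrix] = []
    obs_rows = []
    for ci, cohort in enumerate(cohort_ids):
        tech = cfg.technology_per_cohort[ci]
        depth_base = _TENX_BASE_DEPTH * (
            _SMARTSEQ2_DEPTH_FACTOR if tech == "smartseq2" else 1.0
        )
        for group in cfg.disease_groups:
            eff = _disease_effect_scale(group)
            for di in range(cfg.donors_per_cohort_per_group):
                donor = f"{cohort}_{group}_d{di + 1:02d}"
                noise_scale = cfg.t2d_donor_noise_scale if group == "T2D" else 1.0
                z = rng.normal(0.0, cfg.hub_latent_sd) * noise_scale
                # donor biological variation: a small genome-wide term plus a
                # larger hub-module-specific term that, with the shared latent
                # factor, realizes the configured hub correlation
                donor_noise = rng.normal(0.0, cfg.background_donor_sd, n_genes)
                hub_noise = rng.normal(0.0, s * noise_scale, len(hub_module))

                log_r = log_rate + cohort_bias[ci] + donor_noise
                log_r[hub_module] += w * z + hub_noise
                log_r[robust_idx] += eff * cfg.robust_log2fc * ln2 * robust_sign
                log_r[private_idx[ci]] += (
                    eff * cfg.robust_log2fc * ln2 * private_sign[ci]
                )
                log_r[hub_idx] += eff * cfg.hub_t2d_log2fc * ln2
                rate = np.exp(log_r)

                # HbA1c built from the donor's hub-gene log deviation so the
                # donor-level correlation is hba1c_expression_corr by design
                hub_dev = (w * z + hub_noise[0]) / math.sqrt(
                    w * w * cfg.hub_latent_sd**2 + s * s
                )
                rho_h = cfg.hba1c_expression_corr
                hba1c = 5.4 + 1.3 * (
                    rho_h * hub_dev + math.sqrt(max(0.0, 1 - rho_h**2)) * rng.normal()
                )

                n_cells = int(
                    rng.integers(cfg.cells_per_donor[0], cfg.cells_per_donor[1] + 1)
                )
                celltypes = rng.choice(len(CELL_TYPES), size=n_cells, p=props)
                depth = depth_base * np.exp(
                    rng.normal(0.0, _DEPTH_LOGNORMAL_SD, n_cells)
                )
                jackpot = rng.random(n_cells) < cfg.frac_jackpot_cells
                depth[jackpot] *= _JACKPOT_DEPTH_FACTOR
                high_mito = rng.random(n_cells) < cfg.frac_high_mito_cells

                counts = np.empty((n_cells, n_genes), dtype=np.int32)
                for ti in range(len(CELL_TYPES)):
                    for hm in (False, True):
                        sel = (celltypes == ti) & (high_mito == hm)
                        if not sel.any():
                            continue
                        r = rate.copy()
                        r[marker_idx[CELL_TYPES[ti]]] *= _MARKER_UPLIFT
                        if hm:
                            r[mito_idx] *= _HIGH_MITO_BOOST
                        p = r / r.sum()
                        mean = depth[sel, None] * p[None, :]
                        lam = rng.gamma(cfg.nb_dispersion, mean / cfg.nb_dispersion)
                        counts[sel] = rng.poisson(lam).astype(np.int32)

                blocks.append(sparse.csr_matrix(counts))
                for k in range(n_cells):
                    obs_rows.append(
                        (
                            f"{donor}_c{k + 1:04d}",
                            donor,
                            cohort,
                            tech,
                            group,
                            CELL_TYPES[celltypes[k]],
                            hba1c,
                        )
                    )
                donor_rows.append(
                    {
                        "donor_id": donor,
                        "cohort_id": cohort,
                        "technology": tech,
                        "disease_true": group,
                        "disease": group,
                        "hba1c": hba1c,
                        "n_cells": n_cells,
                    }
                )

    donors = pd.DataFrame(donor_rows).set_index("donor_id", drop=False)
    obs = pd.DataFrame(
        obs_rows,
        columns=[
            "cell_id",
            "donor_id",
            "cohort_id",
            "technology",
            "disease",
            "celltype_true",
            "hba1c",
        ],
    ).set_index("cell_id")

    # outlier donors: swap the annotated ND/T2D label after expression is
    # drawn, so that expression contradicts annotation
    swap = {"ND": "T2D", "T2D": "ND"}
    eligible = donors.index[donors["disease_true"].isin(swap)].to_numpy()
    n_out = round(cfg.frac_outlier_donors * len(eligible))
    outliers: dict[str, str] = {}
    if n_out > 0:
        for donor in rng.choice(eligible, size=n_out, replace=False):
            true = donors.at[donor, "disease_true"]
            donors.at[donor, "disease"] = swap[true]
            obs.loc[obs["donor_id"] == donor, "disease"] = swap[true]
            outliers[donor] = true

    X = sparse.vstack(blocks, format="csr")
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(names, name="gene_id")))

    truth = GroundTruth(
        robust_de={names[g]: int(sg) for g, sg in zip(robust_idx, robust_sign)},
        private_de={
            cohort_ids[ci]: {
                names[g]: int(sg) for g, sg in zip(private_idx[ci], private_sign[ci])
            }
            for ci in range(cfg.n_cohorts)
        },
        hub_gene=HUB_GENE,
        hub_partners=[str(names[g]) for g in partner_idx],
        hub_correlation=true_rho,
        outlier_donors=outliers,
        donors=donors,
    )
    return adata, truth


def write_cohorts(adata: ad.AnnData, truth: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Write the simulated dataset as MTX + TSV + ground_truth.json."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = _io.write_matrix(adata, outdir)
    gt_path = outdir / "ground_truth.json"
    truth.to_json(gt_path)
    paths["ground_truth"] = gt_path
    return paths
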