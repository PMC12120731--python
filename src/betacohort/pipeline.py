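"""End-to-end orchestration: simulate -> qc -> donor-cv -> de -> correlate -> subpop.

Every numeric threshold used anywhere in the analysis lives in one
:class:`PipelineConfig` under a named key, so deviations from the defaults
are explicit, and a run manifest records seeds, thresholds and the
cell/donor/gene counts surviving each stage.  Identical config + seed yields
byte-identical stage outputs and manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import (
    ShuffleConfig,
    build_pseudobulk,
    filter_expressed_genes,
    group_cv,
    shuffled_correlation,
)
from .donor_cv import CVConfig, loo_donor_cv, retained_donors
from .hurdle import hurdle_test, robust_intersection
from .io import read_matrix
from .qc import QCConfig, assign_cell_types, filter_cells, ln_tpm1
from .simulate import MARKER_NAMES, SimulationConfig, generate_cohorts, write_cohorts
from .subpop import median_split

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "donor_cv", "de", "correlate", "subpop")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All stage configs plus the anchor gene and global seed."""

    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    input_dir: str | None = None  # read instead of simulating when set
    qc: QCConfig = field(default_factory=QCConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    shuffle: ShuffleConfig = field(default_factory=ShuffleConfig)
    de_alpha: float = 0.05
    min_cohorts: int = 4
    require_consistent_direction: bool = True
    anchor_gene: str = "ZNT8"
    seed: int = 0
    outdir: str = "betacohort_run"

    def __post_init__(self) -> None:
        # one global seed drives every stage unless a stage seed was set
        if self.simulation is not None and isinstance(self.simulation, SimulationConfig):
            self.simulation.seed = self.simulation.seed or self.seed
        self.cv.seed = self.cv.seed or self.seed
        self.shuffle.seed = self.shuffle.seed or self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is None:
            d["simulation"] = None
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            sim = dict(d["simulation"])
            if "cells_per_donor" in sim:
                sim["cells_per_donor"] = tuple(sim["cells_per_donor"])
            if "disease_groups" in sim:
                sim["disease_groups"] = tuple(sim["disease_groups"])
            d["simulation"] = SimulationConfig(**sim)
        if isinstance(d.get("qc"), dict):
            d["qc"] = QCConfig(**d["qc"])
        if isinstance(d.get("cv"), dict):
            d["cv"] = CVConfig(**d["cv"])
        if isinstance(d.get("shuffle"), dict):
            d["shuffle"] = ShuffleConfig(**d["shuffle"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages in dependency order; return the manifest dict.

    Outputs under ``cfg.outdir``: simulated MTX bundle (when simulating),
    qc_table.tsv, donor_cv_report.tsv, de_<cohort>.tsv, robust_genes.tsv,
    correlation.tsv, subpop_per_group.tsv / subpop_per_cohort.tsv and
    manifest.json.  On stage failure a status.json naming the stage is
    written and :class:`PipelineError` is raised; earlier outputs remain.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "anchor_gene": cfg.anchor_gene,
        "thresholds": {
            "qc_min_genes": cfg.qc.min_genes,
            "qc_mito_max_tenx": cfg.qc.mito_max_tenx,
            "qc_mito_max_smartseq2": cfg.qc.mito_max_smartseq2,
            "qc_top_read_quantile": cfg.qc.top_read_quantile,
            "cv_accuracy_threshold": cfg.cv.accuracy_threshold,
            "de_alpha": cfg.de_alpha,
            "de_min_cohorts": cfg.min_cohorts,
            "pb_min_cells_tenx": cfg.shuffle.min_cells_tenx,
            "pb_min_cells_smartseq2": cfg.shuffle.min_cells_smartseq2,
            "pb_mean_tpm_min": cfg.shuffle.mean_tpm_min,
            "corr_n_shuffles": cfg.shuffle.n_shuffles,
            "corr_donor_fraction": cfg.shuffle.donor_fraction,
            "corr_r_threshold": cfg.shuffle.r_threshold,
        },
        "stages": {},
    }
    stage = "simulate"
    try:
        if cfg.input_dir is not None:
            stage = "read"
            adata = read_matrix(cfg.input_dir)
            truth = None
        else:
            if cfg.simulation is None:
                raise ValueError("either input_dir or a simulation block is required")
            adata, truth = generate_cohorts(cfg.simulation)
            write_cohorts(adata, truth, out / "simulated")
        manifest["stages"][stage] = {
            "n_cells": int(adata.n_obs),
            "n_genes": int(adata.n_vars),
            "n_donors": int(adata.obs["donor_id"].nunique()),
        }

        stage = "qc"
        filtered, qc_table = filter_cells(adata, cfg.qc)
        qc_table.to_csv(out / "qc_table.tsv", sep="\t")
        norm = ln_tpm1(filtered.X)
        n_markers = (
            cfg.simulation.n_marker_genes_per_celltype if cfg.simulation else None
        )
        markers = {
            ct: [g for g in names[: (n_markers or len(names))] if g in filtered.var_names]
            for ct, names in MARKER_NAMES.items()
        }
        labels = assign_cell_types(norm, filtered.var_names, markers)
        filtered.obs["celltype"] = labels
        manifest["stages"]["qc"] = {
            "n_cells_in": int(adata.n_obs),
            "n_cells_out": int(filtered.n_obs),
            "removed_min_genes": int((~qc_table["pass_min_genes"]).sum()),
            "removed_mito": int((~qc_table["pass_mito"]).sum()),
            "removed_depth": int((~qc_table["pass_depth"]).sum()),
        }

        beta = filtered[filtered.obs["celltype"] == "beta"].copy()
        beta_norm = ln_tpm1(beta.X)

        stage = "donor_cv"
        report = loo_donor_cv(beta_norm, beta.obs, cfg.cv)
        report.to_csv(out / "donor_cv_report.tsv", sep="\t", index=False)
        kept_donors = set(retained_donors(report))
        # donors in cohorts skipped by CV (single disease group) pass through
        uncovered = set(beta.obs["donor_id"]) - set(report["donor_id"])
        kept_donors |= uncovered
        keep_mask = beta.obs["donor_id"].isin(kept_donors).to_numpy()
        beta_kept = beta[keep_mask].copy()
        beta_kept_norm = ln_tpm1(beta_kept.X)
        manifest["stages"]["donor_cv"] = {
            "n_donors_in": int(beta.obs["donor_id"].nunique()),
            "n_donors_out": int(beta_kept.obs["donor_id"].nunique()),
            "n_flagged": int(report["is_outlier"].sum()),
            "n_cells_out": int(beta_kept.n_obs),
        }

        stage = "de"
        n_cohorts_avail = beta_kept.obs["cohort_id"].nunique()
        if cfg.min_cohorts > n_cohorts_avail:
            raise ValueError(
                f"min_cohorts={cfg.min_cohorts} exceeds available cohorts "
                f"({n_cohorts_avail})"
            )
        tables = []
        for cohort in pd.unique(beta_kept.obs["cohort_id"]):
            sel = (beta_kept.obs["cohort_id"] == cohort).to_numpy()
            dis = beta_kept.obs.loc[sel, "disease"]
            if not {"ND", "T2D"} <= set(dis):
                logger.warning("cohort %s lacks both groups; DE skipped", cohort)
                continue
            tab = hurdle_test(
                beta_kept_norm[sel], dis.to_numpy(), beta_kept.var_names, cohort_id=cohort
            )
            tab.to_csv(out / f"de_{cohort}.tsv", sep="\t", index=False)
            tables.append(tab)
        robust = robust_intersection(
            tables,
            min_cohorts=cfg.min_cohorts,
            alpha=cfg.de_alpha,
            require_consistent_direction=cfg.require_consistent_direction,
        )
        robust.table.to_csv(out / "robust_genes.tsv", sep="\t", index=False)
        manifest["stages"]["de"] = {
            "n_cohorts_tested": len(tables),
            "n_robust_genes": int(len(robust.table)),
        }

        stage = "correlate"
        pb = build_pseudobulk(
            beta_kept.X, beta_kept.obs, beta_kept.var_names, cfg.shuffle
        )
        pb = filter_expressed_genes(pb, cfg.shuffle.mean_tpm_min)
        corr = shuffled_correlation(pb, cfg.anchor_gene, cfg.shuffle)
        corr.to_csv(out / "correlation.tsv", sep="\t", index=False)
        cv_by_group = group_cv(pb, cfg.anchor_gene)
        manifest["stages"]["correlate"] = {
            "n_donors": int(pb.tpm.shape[0]),
            "n_genes_expressed": int(pb.tpm.shape[1]),
            "n_correlated_above_threshold": int(
                (
                    (corr["pearson_avg"] > cfg.shuffle.r_threshold)
                    & (corr["gene_id"] != cfg.anchor_gene)
                ).sum()
            ),
            "anchor_cv_by_group": {k: float(v) for k, v in cv_by_group.items()},
        }

        stage = "subpop"
        shift = median_split(
            beta_kept_norm, beta_kept.obs, beta_kept.var_names, cfg.anchor_gene
        )
        shift.per_group.to_csv(out / "subpop_per_group.tsv", sep="\t", index=False)
        shift.per_cohort.to_csv(out / "subpop_per_cohort.tsv", sep="\t", index=False)
        manifest["stages"]["subpop"] = {
            "n_cohorts": int(len(shift.per_cohort)),
            "n_delta_positive": int((shift.per_cohort["delta"] > 0).sum()),
        }
    except Exception as exc:
        (out / "status.json").write_text(
            json.dumps({"status": "error", "stage": stage, "message": str(exc)}, indent=1)
        )
        raise PipelineError(stage, str(exc)) from exc

    # filter-funnel monotonicity is a structural guarantee; assert it
    assert manifest["stages"]["qc"]["n_cells_out"] <= manifest["stages"]["qc"]["n_cells_in"]
    assert (
        manifest["stages"]["donor_cv"]["n_donors_out"]
        <= manifest["stages"]["donor_cv"]["n_donors_in"]
    )

    manifest["status"] = "complete"
    (out / "status.json").write_text(json.dumps({"status": "complete"}, indent=1))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
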