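"""Anchor-high / anchor-low β-cell subpopulations by per-cohort median split.

Each cohort's β cells are split at the cohort-wide median ln(TPM+1) of the
anchor gene: a cell is "high" when strictly above the median, ties fall to
"low" so that with zero-inflated genes the high class is strictly
expressing.  The composition shift is the difference in high-cell proportion
between T2D and ND within each cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)


@dataclass
class SubpopulationShift:
    """Median-split summary.

    ``per_group``: one row per (cohort, disease) with n_cells, n_high,
    prop_high, prop_low.  ``per_cohort``: cohort, median (on ln(TPM+1)) and
    delta = T2D high proportion minus ND high proportion.
    """

    anchor: str
    per_group: pd.DataFrame
    per_cohort: pd.DataFrame


def median_split(
    expr: sparse.spmatrix | np.ndarray,
    annotations: pd.DataFrame,
    gene_ids,
    anchor: str,
) -> SubpopulationShift:
    """Split β cells at the per-cohort median anchor expression.

    ``expr`` is normalized (ln(TPM+1)) cells x genes; ``annotations`` needs
    cohort_id and disease per cell.  The median is computed over all of the
    cohort's cells (every disease group pooled); cohorts missing either ND
    or T2D are skipped with a warning.
    """
    gene_index = pd.Index(gene_ids)
    if anchor not in gene_index:
        raise ValueError(f"anchor gene {anchor!r} absent from matrix")
    ai = gene_index.get_loc(anchor)
    x = (
        np.asarray(expr[:, ai].todense()).ravel()
        if sparse.issparse(expr)
        else np.asarray(expr)[:, ai]
    )
    if annotations.shape[0] != len(x):
        raise ValueError("annotations must cover all cells")

    group_rows = []
    cohort_rows = []
    for cohort in pd.unique(annotations["cohort_id"]):
        sel = (annotations["cohort_id"] == cohort).to_numpy()
        dis = annotations.loc[sel, "disease"]
        present = set(dis)
        if not {"ND", "T2D"} <= present:
            logger.warning(
                "cohort %s skipped: needs both ND and T2D cells (has %s)",
                cohort,
                sorted(present),
            )
            continue
        vals = x[sel]
        med = float(np.median(vals))
        high = vals > med  # strict: ties at the median are "low"
        props = {}
        for g in sorted(present):
            gi = (dis == g).to_numpy()
            n = int(gi.sum())
            n_high = int(high[gi].sum())
            props[g] = n_high / n
            group_rows.append(
                {
                    "cohort_id": cohort,
                    "disease": g,
                    "n_cells": n,
                    "n_high": n_high,
                    "prop_high": n_high / n,
                    "prop_low": 1.0 - n_high / n,
                }
            )
        cohort_rows.append(
            {
                "cohort_id": cohort,
                "median": med,
                "delta": props["T2D"] - props["ND"],
            }
        )
    return SubpopulationShift(
        anchor=anchor,
        per_group=pd.DataFrame(
            group_rows,
            columns=["cohort_id", "disease", "n_cells", "n_high", "prop_high", "prop_low"],
        ),
        per_cohort=pd.DataFrame(cohort_rows, columns=["cohort_id", "median", "delta"]),
    )
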