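"""Two-part hurdle differential expression and cross-cohort intersection.

Each gene is modelled in two parts on normalized expression: a Bernoulli
(logistic) component for whether the gene is detected in a cell, and a
Gaussian component for the magnitude of its positive values.  Both parts are
compared against intercept-only fits by likelihood ratio and the two
statistics are summed into a chi-square with summed degrees of freedom — the
hurdle construction popularized for single-cell DE testing.  With a single
binary covariate (ND vs T2D) both likelihood ratios have closed forms:

* detection: binomial log-likelihood of group-wise detection rates versus the
  pooled rate, ``2 * (ll1 - ll0)`` on 1 df;
* magnitude: ``m * ln(RSS0 / RSS1)`` over the ``m`` detected cells, group
  means versus pooled mean, 1 df.

A part that is degenerate (no detection variation pooled across groups, or
all detected cells in one group) contributes 0 with a df reduction.  This
makes the per-cohort test a handful of vectorized array reductions, exact for
the model, with no per-gene iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

logger = logging.getLogger(__name__)

_LOG2 = np.log(2.0)
_FC_PSEUDOCOUNT = 0.01  # on mean ln(TPM+1) when one group has no detection


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x * np.log(np.maximum(y, 1e-300)), 0.0)


def _binomial_ll(k: np.ndarray, n: float | np.ndarray) -> np.ndarray:
    """Maximized Bernoulli log-likelihood for k successes of n (per gene)."""
    n = np.broadcast_to(np.asarray(n, dtype=float), np.shape(k))
    p = np.divide(k, n, out=np.zeros_like(n, dtype=float), where=n > 0)
    return _xlogy(k, p) + _xlogy(n - k, 1.0 - p)


def hurdle_test(
    expr: sparse.spmatrix | np.ndarray,
    groups,
    gene_ids,
    cohort_id: str | None = None,
    group_order: tuple[str, str] = ("ND", "T2D"),
    min_cells_detected: int = 3,
) -> pd.DataFrame:
    """Hurdle LRT of every gene between two groups within one cohort.

    Parameters
    ----------
    expr
        Normalized expression, cells x genes (ln(TPM+1) recommended).
    groups
        Per-cell labels; exactly the two values of ``group_order`` must be
        present.  Effects are reported as ``group_order[1]`` versus
        ``group_order[0]`` (T2D vs ND by default).
    min_cells_detected
        Genes detected in fewer cells than this are dropped before testing
        (they never enter the multiple-testing correction).

    Returns a table with log2 fold change of the magnitude component,
    detection-rate difference, LRT statistic, df, p, BH-adjusted p, and
    direction ("up"/"down", ties broken by the detection-rate difference).
    """
    groups = np.asarray(groups)
    present = set(np.unique(groups))
    if not set(group_order) <= present:
        raise ValueError(
            f"both groups {group_order} required, found {sorted(present)}"
        )
    extra = present - set(group_order)
    if extra:
        keep = np.isin(groups, group_order)
        expr = expr[keep]
        groups = groups[keep]

    X = expr.tocsr().astype(np.float64) if sparse.issparse(expr) else np.asarray(
        expr, dtype=np.float64
    )
    g1 = groups == group_order[1]
    n0 = float((~g1).sum())
    n1 = float(g1.sum())

    if sparse.issparse(X):
        D = (X > 0).astype(np.float64)
        k1 = np.asarray(D[np.asarray(g1)].sum(axis=0)).ravel()
        k0 = np.asarray(D.sum(axis=0)).ravel() - k1
        s1 = np.asarray(X[np.asarray(g1)].sum(axis=0)).ravel()
        s0 = np.asarray(X.sum(axis=0)).ravel() - s1
        X2 = X.multiply(X)
        q1 = np.asarray(X2[np.asarray(g1)].sum(axis=0)).ravel()
        q0 = np.asarray(X2.sum(axis=0)).ravel() - q1
    else:
        D = X > 0
        k1 = D[g1].sum(axis=0).astype(float)
        k0 = D[~g1].sum(axis=0).astype(float)
        s1 = X[g1].sum(axis=0)
        s0 = X[~g1].sum(axis=0)
        q1 = (X[g1] ** 2).sum(axis=0)
        q0 = (X[~g1] ** 2).sum(axis=0)

    gene_ids = np.asarray(gene_ids, dtype=object)
    tested = (k0 + k1) >= min_cells_detected
    if not tested.all():
        logger.info(
            "dropping %d gene(s) detected in fewer than %d cells",
            int((~tested).sum()),
            min_cells_detected,
        )
    k0, k1, s0, s1, q0, q1 = (a[tested] for a in (k0, k1, s0, s1, q0, q1))
    ids = gene_ids[tested]
    m = k0 + k1

    # detection component
    ll_full = _binomial_ll(k0, n0) + _binomial_ll(k1, n1)
    ll_null = _binomial_ll(m, n0 + n1)
    lrt_d = 2.0 * (ll_full - ll_null)
    df_d = ((m > 0) & (m < n0 + n1)).astype(int)
    lrt_d = np.where(df_d == 1, np.maximum(lrt_d, 0.0), 0.0)

    # magnitude component over detected cells
    with np.errstate(invalid="ignore", divide="ignore"):
        rss1 = (q0 - s0**2 / np.maximum(k0, 1)) + (q1 - s1**2 / np.maximum(k1, 1))
        rss0 = (q0 + q1) - (s0 + s1) ** 2 / np.maximum(m, 1)
    df_c = ((k0 > 0) & (k1 > 0) & (m > 2)).astype(int)
    eps = 1e-12
    lrt_c = np.where(
        df_c == 1,
        m * np.log(np.maximum(rss0, 0.0) + eps) - m * np.log(np.maximum(rss1, 0.0) + eps),
        0.0,
    )
    lrt_c = np.maximum(lrt_c, 0.0)

    lrt = lrt_d + lrt_c
    df = df_d + df_c
    p = np.where(df > 0, stats.chi2.sf(lrt, np.maximum(df, 1)), 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean0 = np.divide(s0, k0, out=np.zeros_like(s0), where=k0 > 0)
        mean1 = np.divide(s1, k1, out=np.zeros_like(s1), where=k1 > 0)
    both = (k0 > 0) & (k1 > 0)
    log2fc = np.where(both, (mean1 - mean0) / _LOG2, 0.0)
    # one group undetected: fall back to all-cell group means with pseudocount
    fallback = ~both
    if fallback.any():
        all0 = s0 / n0
        all1 = s1 / n1
        log2fc[fallback] = np.log2(
            (all1[fallback] + _FC_PSEUDOCOUNT) / (all0[fallback] + _FC_PSEUDOCOUNT)
        )
    det_diff = k1 / n1 - k0 / n0
    direction = np.where(
        log2fc != 0, np.where(log2fc > 0, "up", "down"),
        np.where(det_diff >= 0, "up", "down"),
    )

    out = pd.DataFrame(
        {
            "gene_id": ids,
            "cohort_id": cohort_id if cohort_id is not None else "",
            "log2fc": log2fc,
            "detection_diff": det_diff,
            "lrt": lrt,
            "df": df,
            "p": p,
            "p_adj": bh_adjust(p),
            "direction": direction,
            "fc_pseudocount": fallback,
        }
    )
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    NaN entries propagate as NaN and are excluded from the ranking; adjusted
    values are monotone in p and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    n = pv.size
    if n == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(n)
    res[order] = np.minimum(adj, 1.0)
    out[valid] = res
    return out


@dataclass
class RobustGeneSet:
    """Genes significant in at least ``min_cohorts`` cohorts."""

    table: pd.DataFrame  # gene_id, n_cohorts_significant, consensus_direction, cohorts
    min_cohorts: int
    alpha: float
    require_consistent_direction: bool = True

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])


def robust_intersection(
    tables: list[pd.DataFrame],
    min_cohorts: int = 4,
    alpha: float = 0.05,
    require_consistent_direction: bool = True,
) -> RobustGeneSet:
    """Intersect per-cohort DE tables into the robust gene set.

    A gene qualifies when its BH-adjusted p is below ``alpha`` in at least
    ``min_cohorts`` cohorts and — when direction consistency is required —
    its effect direction agrees in every cohort where it is significant.
    Genes absent from some cohorts are counted only where they were tested.
    """
    if len(tables) < min_cohorts:
        raise ValueError(
            f"need at least min_cohorts={min_cohorts} cohort tables, got {len(tables)}"
        )
    allt = pd.concat(tables, ignore_index=True)
    sig = allt[allt["p_adj"] < alpha]
    rows = []
    for gene, sub in sig.groupby("gene_id", sort=True):
        n_sig = len(sub)
        if n_sig < min_cohorts:
            continue
        dirs = set(sub["direction"])
        if require_consistent_direction and len(dirs) > 1:
            continue
        signed = np.where(sub["direction"] == "up", 1, -1).sum()
        if signed == 0:
            logger.info("gene %s has tied direction votes; excluded", gene)
            continue
        rows.append(
            {
                "gene_id": gene,
                "n_cohorts_significant": n_sig,
                "consensus_direction": "up" if signed > 0 else "down",
                "cohorts": ",".join(sorted(sub["cohort_id"].astype(str))),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "n_cohorts_significant", "consensus_direction", "cohorts"],
    )
    return RobustGeneSet(
        table=table,
        min_cohorts=min_cohorts,
        alpha=alpha,
        require_consistent_direction=require_consistent_direction,
    )
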