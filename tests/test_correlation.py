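"""Pseudobulk construction, shuffled correlation, covariates, CV summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from betacohort.correlation import (
    DonorPseudobulk,
    ShuffleConfig,
    build_pseudobulk,
    correlate_covariate,
    filter_expressed_genes,
    group_cv,
    permutation_null_pvalues,
    shuffled_correlation,
)
from betacohort.simulate import SimulationConfig, generate_cohorts


def _cells(donor_cells: dict[str, int], technology="tenx", n_genes=3, seed=0):
    """Counts + annotations with a fixed number of cells per donor."""
    rng = np.random.default_rng(seed)
    rows, ann = [], []
    for donor, n in donor_cells.items():
        for i in range(n):
            rows.append(rng.integers(1, 10, n_genes))
            ann.append((donor, "c1", technology, "ND"))
    counts = np.array(rows)
    annotations = pd.DataFrame(
        ann, columns=["donor_id", "cohort_id", "technology", "disease"]
    )
    return counts, annotations


class TestBuildPseudobulk:
    def test_strict_more_than_50_cells_for_tenx(self):
        counts, ann = _cells({"d50": 50, "d51": 51})
        pb = build_pseudobulk(counts, ann, ["a", "b", "c"])
        assert list(pb.donors.index) == ["d51"]

    def test_strict_more_than_10_cells_for_smartseq2(self):
        counts, ann = _cells({"d10": 10, "d11": 11}, technology="smartseq2")
        pb = build_pseudobulk(counts, ann, ["a", "b", "c"])
        assert list(pb.donors.index) == ["d11"]

    def test_single_expressed_gene_gets_full_million(self):
        counts = np.zeros((60, 3), dtype=int)
        counts[:, 1] = 4
        _, ann = _cells({"d": 60})
        pb = build_pseudobulk(counts, ann, ["a", "b", "c"])
        np.testing.assert_allclose(pb.tpm.to_numpy(), [[0.0, 1e6, 0.0]])

    def test_pseudobulk_tpm_equals_tpm_of_summed_counts(self):
        counts, ann = _cells({"d": 55}, n_genes=5, seed=3)
        pb = build_pseudobulk(counts, ann, list("abcde"))
        summed = counts.sum(axis=0)
        np.testing.assert_allclose(
            pb.tpm.to_numpy().ravel(), summed / summed.sum() * 1e6, rtol=1e-12
        )

    def test_rows_sum_to_one_million(self, sim_small):
        adata, _ = sim_small
        beta = adata[(adata.obs["celltype_true"] == "beta").to_numpy()]
        pb = build_pseudobulk(
            beta.X, beta.obs, beta.var_names, ShuffleConfig(min_cells_tenx=5, min_cells_smartseq2=5)
        )
        np.testing.assert_allclose(pb.tpm.sum(axis=1), 1e6, rtol=1e-6)

    def test_no_surviving_donor_names_filter(self):
        counts, ann = _cells({"d": 20})
        with pytest.raises(ValueError, match="cell-count"):
            build_pseudobulk(counts, ann, ["a", "b", "c"])


def _pb(tpm: np.ndarray, genes, disease=None, technology="tenx", **covars):
    n = tpm.shape[0]
    donors = pd.DataFrame(
        {
            "donor_id": [f"d{i}" for i in range(n)],
            "cohort_id": ["c1"] * n,
            "technology": [technology] * n,
            "disease": disease if disease is not None else ["ND"] * n,
            "n_cells": [100] * n,
            **covars,
        }
    ).set_index("donor_id", drop=False)
    return DonorPseudobulk(
        tpm=pd.DataFrame(tpm, index=donors.index, columns=pd.Index(genes, name="gene_id")),
        donors=donors,
    )


class TestFilterExpressedGenes:
    def test_strictly_greater_than_one_mean_tpm(self):
        tpm = np.tile([1.0, 1.01, 0.5], (10, 1))
        pb = filter_expressed_genes(_pb(tpm, ["at", "above", "below"]))
        assert list(pb.tpm.columns) == ["above"]

    def test_single_high_donor_can_carry_a_gene(self):
        tpm = np.zeros((100, 2))
        tpm[:, 0] = 10.0
        tpm[0, 1] = 1e6  # mean 1e4 across 100 donors
        pb = filter_expressed_genes(_pb(tpm, ["g1", "g2"]))
        assert "g2" in pb.tpm.columns

    def test_empty_result_raises(self):
        with pytest.raises(ValueError, match="mean TPM"):
            filter_expressed_genes(_pb(np.full((5, 2), 0.5), ["a", "b"]))


class TestShuffledCorrelation:
    def _random_pb(self, n_donors=40, n_genes=6, seed=0):
        rng = np.random.default_rng(seed)
        tpm = rng.gamma(2.0, 50.0, size=(n_donors, n_genes))
        return _pb(tpm, [f"g{i}" for i in range(n_genes)])

    def test_anchor_against_itself_is_one_in_every_shuffle(self):
        pb = self._random_pb()
        out = shuffled_correlation(pb, "g0", ShuffleConfig(seed=1))
        row = out[out["gene_id"] == "g0"].iloc[0]
        assert row["pearson_avg"] == pytest.approx(1.0, abs=1e-12)
        shuffle_cols = [c for c in out.columns if c.startswith("pearson_s")]
        assert all(row[c] == pytest.approx(1.0, abs=1e-12) for c in shuffle_cols)

    def test_affine_anticorrelated_gene_is_minus_one(self):
        pb = self._random_pb()
        ln_anchor = np.log1p(pb.tpm["g0"])
        pb.tpm["g1"] = np.expm1(ln_anchor.max() + 1.0 - ln_anchor)
        out = shuffled_correlation(pb, "g0", ShuffleConfig(seed=1))
        assert out.loc[out["gene_id"] == "g1", "pearson_avg"].iloc[0] == pytest.approx(
            -1.0, abs=1e-9
        )
        assert out.loc[out["gene_id"] == "g1", "spearman_avg"].iloc[0] == pytest.approx(
            -1.0, abs=1e-9
        )

    def test_full_fraction_single_shuffle_equals_plain_pearson(self):
        pb = self._random_pb(seed=2)
        out = shuffled_correlation(
            pb, "g0", ShuffleConfig(donor_fraction=1.0, n_shuffles=1, seed=2)
        )
        L = pb.lntpm1().to_numpy()
        for j, gene in enumerate(pb.tpm.columns):
            expected = np.corrcoef(L[:, 0], L[:, j])[0, 1]
            got = out.loc[out["gene_id"] == gene, "pearson_avg"].iloc[0]
            assert got == pytest.approx(expected, abs=5e-15)

    def test_deterministic_given_seed_and_insensitive_to_donor_order(self):
        pb = self._random_pb(seed=3)
        a = shuffled_correlation(pb, "g0", ShuffleConfig(seed=7))
        b = shuffled_correlation(pb, "g0", ShuffleConfig(seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_anchor_donors_dropped_per_shuffle(self):
        pb = self._random_pb(n_donors=10, seed=4)
        pb.tpm.iloc[:6, 0] = 0.0  # anchor absent in 6 of 10 donors
        out = shuffled_correlation(
            pb, "g0", ShuffleConfig(donor_fraction=1.0, n_shuffles=1, seed=0)
        )
        # only the 4 anchor-expressing donors can enter
        assert out["n_eff"].iloc[0] == 4

    def test_all_shuffles_unusable_raises(self):
        pb = self._random_pb(n_donors=10, seed=5)
        pb.tpm.iloc[:, 0] = 0.0
        with pytest.raises(ValueError, match="usable donors"):
            shuffled_correlation(pb, "g0", ShuffleConfig(seed=0))

    def test_spearman_invariant_under_monotone_transform(self):
        pb = self._random_pb(seed=6)
        out1 = shuffled_correlation(pb, "g0", ShuffleConfig(seed=9))
        pb2 = self._random_pb(seed=6)
        # cubing TPM is monotone on ln(TPM+1) ranks
        pb2.tpm["g2"] = pb2.tpm["g2"] ** 3
        out2 = shuffled_correlation(pb2, "g0", ShuffleConfig(seed=9))
        assert out1.loc[out1["gene_id"] == "g2", "spearman_avg"].iloc[0] == pytest.approx(
            out2.loc[out2["gene_id"] == "g2", "spearman_avg"].iloc[0], abs=1e-12
        )

    def test_averaged_equals_mean_of_per_shuffle_values(self):
        pb = self._random_pb(seed=8)
        out = shuffled_correlation(pb, "g0", ShuffleConfig(seed=3))
        shuffle_cols = [c for c in out.columns if c.startswith("pearson_s")]
        np.testing.assert_allclose(
            out[shuffle_cols].mean(axis=1), out["pearson_avg"], rtol=1e-12
        )

    def test_tbased_pvalues_agree_with_permutation_oracle(self):
        """On donor-level data the analytic p of the averaged r matches a
        donor-label permutation null at the decision level."""
        rng = np.random.default_rng(10)
        n = 60
        latent = rng.normal(0, 1, n)
        tpm = np.empty((n, 8))
        tpm[:, 0] = np.expm1(5 + latent)
        for j in range(1, 4):  # truly correlated partners
            tpm[:, j] = np.expm1(5 + latent + rng.normal(0, 0.6, n))
        for j in range(4, 8):  # null genes
            tpm[:, j] = np.expm1(5 + rng.normal(0, 1, n))
        pb = _pb(tpm, [f"g{i}" for i in range(8)])
        cfg = ShuffleConfig(seed=4)
        t_based = shuffled_correlation(pb, "g0", cfg).set_index("gene_id")
        perm = permutation_null_pvalues(pb, "g0", cfg, n_permutations=500).set_index(
            "gene_id"
        )
        for g in [f"g{i}" for i in range(1, 4)]:
            assert t_based.loc[g, "p"] < 0.01
            assert perm.loc[g, "p_perm"] < 0.02
        for g in [f"g{i}" for i in range(4, 8)]:
            agree = (t_based.loc[g, "p"] < 0.05) == (perm.loc[g, "p_perm"] < 0.05)
            assert agree or abs(t_based.loc[g, "p"] - perm.loc[g, "p_perm"]) < 0.1


class TestCovariateAndCV:
    def test_covariate_equal_to_expression_gives_r_one(self):
        tpm = np.tile(np.arange(1.0, 11.0)[:, None] * 100, (1, 2))
        pb = _pb(tpm, ["g1", "g2"], hba1c=np.log1p(tpm[:, 0]))
        r, p, n = correlate_covariate(pb, "g1", "hba1c")
        assert r == pytest.approx(1.0, abs=1e-12)
        assert n == 10

    def test_two_donors_rejected(self):
        pb = _pb(np.array([[1.0, 2.0], [3.0, 4.0]]), ["g1", "g2"], hba1c=[5.0, 6.0])
        with pytest.raises(ValueError, match="complete donors"):
            correlate_covariate(pb, "g1", "hba1c")

    def test_constructed_hba1c_correlation_recovered(self):
        """Generator builds donor HbA1c as 0.8 x scaled anchor + noise; the
        estimate at ~100 donors must sit inside the Fisher-z 95% band."""
        cfg = SimulationConfig(
            n_cohorts=1,
            technology_per_cohort=["tenx"],
            donors_per_cohort_per_group=50,
            cells_per_donor=(150, 250),
            n_genes=400,
            n_marker_genes_per_celltype=3,
            n_robust_de_genes=5,
            n_private_de_genes_per_cohort=5,
            n_hub_correlated_genes=3,
            seed=13,
        )
        adata, truth = generate_cohorts(cfg)
        beta = adata[(adata.obs["celltype_true"] == "beta").to_numpy()]
        pb = build_pseudobulk(beta.X, beta.obs, beta.var_names, ShuffleConfig())
        r, p, n = correlate_covariate(pb, truth.hub_gene, "hba1c")
        z = math.atanh(0.8)
        half = 1.96 / math.sqrt(n - 3)
        lo, hi = math.tanh(z - half), math.tanh(z + half)
        # allow a touch of attenuation from pseudobulk counting noise
        assert lo - 0.05 <= r <= hi

    def test_constant_expression_gives_zero_cv(self):
        pb = _pb(np.full((6, 1), 100.0), ["g"], disease=["ND"] * 3 + ["T2D"] * 3)
        cv = group_cv(pb, "g")
        assert cv["ND"] == 0.0 and cv["T2D"] == 0.0

    def test_hand_computed_cv(self):
        # ln(TPM+1) values (1, 3): sample SD sqrt(2), mean 2
        tpm = np.expm1([[1.0], [3.0], [1.0], [3.0]])
        pb = _pb(tpm, ["g"], disease=["ND", "ND", "T2D", "T2D"])
        cv = group_cv(pb, "g")
        assert cv["ND"] == pytest.approx(math.sqrt(2) / 2, rel=1e-9)

    def test_halved_t2d_donor_variance_lowers_t2d_cv(self):
        wins = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_cohorts=1,
                technology_per_cohort=["tenx"],
                donors_per_cohort_per_group=30,
                cells_per_donor=(60, 100),
                n_genes=300,
                n_marker_genes_per_celltype=3,
                n_robust_de_genes=5,
                n_private_de_genes_per_cohort=5,
                n_hub_correlated_genes=3,
                t2d_donor_noise_scale=0.5,
                seed=seed,
            )
            adata, truth = generate_cohorts(cfg)
            beta = adata[(adata.obs["celltype_true"] == "beta").to_numpy()]
            pb = build_pseudobulk(
                beta.X, beta.obs, beta.var_names, ShuffleConfig(min_cells_tenx=10)
            )
            cv = group_cv(pb, truth.hub_gene)
            wins += cv["T2D"] < cv["ND"]
        assert wins >= 9
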