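"""Pseudobulk aggregation, site-level NB QL models, gene rotation test,
disease-overlap Fisher test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from conftest import make_matrix
from scredit import differential
from scredit.calibration import make_null_pseudobulk
from scredit.differential import PseudobulkTable


def _pb(edited, unedited, phenotypes, regions=None, sites=None):
    edited = np.atleast_2d(np.asarray(edited))
    unedited = np.atleast_2d(np.asarray(unedited))
    G = edited.shape[1]
    samples = pd.DataFrame(
        {
            "sample_id": [f"p{g}" for g in range(G)],
            "subgroup": [f"sg{g}" for g in range(G)],
            "phenotype": phenotypes,
            "region": regions if regions is not None else ["R1"] * G,
            "n_cells": 10,
        }
    )
    if sites is None:
        sites = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(edited.shape[0])],
                "gene_id": "g0",
            }
        )
    return PseudobulkTable(
        edited=edited, unedited=unedited, samples=samples, sites=sites
    )


class TestBuildPseudobulk:
    def test_counts_sum_within_group(self):
        depth = np.array([[4, 6]])
        alt = np.array([[1, 2]])
        m = make_matrix(alt, depth)
        m.cells["subgroup"] = "Ex1"
        m.cells["region"] = "BA8"
        m.cells["phenotype"] = "excitatory"
        pb = differential.build_pseudobulk(m, var_min=-1.0)
        assert pb.edited[0, 0] == 3
        assert pb.unedited[0, 0] == 7

    def test_invariant_sites_removed(self):
        rng = np.random.default_rng(0)
        depth = np.full((2, 40), 10)
        alt = np.vstack(
            [np.full(40, 3), rng.integers(0, 9, size=40)]  # site 0 constant
        )
        m = make_matrix(alt, depth)
        m.cells["subgroup"] = np.repeat([f"sg{k}" for k in range(4)], 10)
        m.cells["region"] = "BA8"
        m.cells["phenotype"] = "excitatory"
        pb = differential.build_pseudobulk(m, var_min=0.2)
        assert pb.n_removed_low_variance == 1
        assert list(pb.sites["site_id"]) == ["s1"]

    def test_sums_match_per_group_loop(self, small_dataset):
        m = small_dataset.matrix
        pb = differential.build_pseudobulk(m, var_min=-1.0)
        alt = m.alt.toarray()
        depth = m.depth.toarray()
        key = m.cells[["subgroup", "region"]].astype(str).agg("|".join, axis=1)
        for gi, g in enumerate(pb.samples["sample_id"]):
            idx = np.flatnonzero((key == g).to_numpy())
            assert (pb.edited[:, gi] == alt[:, idx].sum(axis=1)).all()
            assert (
                pb.unedited[:, gi]
                == (depth[:, idx] - alt[:, idx]).sum(axis=1)
            ).all()

    def test_aggregation_invariance_under_cell_split(self):
        rng = np.random.default_rng(7)
        depth = rng.integers(0, 10, size=(5, 20))
        alt = rng.binomial(depth, 0.3)
        m1 = make_matrix(alt, depth)
        m1.cells["subgroup"] = "sgA"
        m1.cells["region"] = "R1"
        m1.cells["phenotype"] = "excitatory"
        pb1 = differential.build_pseudobulk(m1, var_min=-1.0)
        m2 = make_matrix(alt, depth)
        m2.cells["subgroup"] = ["sgA"] * 10 + ["sgB"] * 10
        m2.cells["region"] = "R1"
        m2.cells["phenotype"] = "excitatory"
        pb2 = differential.build_pseudobulk(m2, var_min=-1.0)
        assert (pb2.edited.sum(axis=1) == pb1.edited.sum(axis=1)).all()
        assert (pb2.unedited.sum(axis=1) == pb1.unedited.sum(axis=1)).all()

    def test_fraction_variance_mode(self):
        depth = np.full((1, 40), 10)
        alt = np.tile(np.repeat([1, 9], 10), 2).reshape(1, 40)
        m = make_matrix(alt, depth)
        m.cells["subgroup"] = np.repeat([f"sg{k}" for k in range(4)], 10)
        m.cells["region"] = "R1"
        m.cells["phenotype"] = "excitatory"
        pb = differential.build_pseudobulk(
            m, var_min=0.05, var_on="fraction"
        )
        assert pb.edited.shape[0] == 1  # fraction variance is large
        with pytest.raises(ValueError, match="var_on"):
            differential.build_pseudobulk(m, var_on="bogus")


class TestFitSiteModels:
    def test_symmetric_counts_give_null_result(self):
        pheno = ["excitatory"] * 2 + ["inhibitory"] * 2
        pb = _pb([[50, 50, 50, 50]], [[50, 50, 50, 50]], pheno)
        res = differential.fit_site_models(pb, adjust=None)
        assert res["log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-8)
        assert res["p"].iloc[0] > 0.99

    def test_label_swap_negates_logfc_keeps_p(self):
        pb = make_null_pseudobulk(3, n_sites=30)
        res1 = differential.fit_site_models(pb)
        swapped = PseudobulkTable(
            edited=pb.edited,
            unedited=pb.unedited,
            samples=pb.samples.assign(
                phenotype=pb.samples["phenotype"].map(
                    {"excitatory": "zz_inh", "inhibitory": "aa_exc"}
                )
            ),
            sites=pb.sites,
        )
        res2 = differential.fit_site_models(swapped)
        assert np.allclose(res1["log2fc"], -res2["log2fc"], atol=1e-6)
        assert np.allclose(res1["p"], res2["p"], atol=1e-6)

    def test_zero_arm_continuity_flagged(self):
        pheno = ["excitatory"] * 2 + ["inhibitory"] * 2
        pb = _pb([[0, 0, 5, 7]], [[40, 45, 35, 33]], pheno)
        res = differential.fit_site_models(pb, adjust=None)
        assert bool(res["continuity"].iloc[0])
        assert np.isfinite(res["p"].iloc[0])

    def test_too_few_pseudoreplicates_errors(self):
        pb = _pb([[5, 5, 5]], [[5, 5, 5]],
                 ["excitatory", "excitatory", "inhibitory"])
        with pytest.raises(ValueError, match="pseudoreplicates"):
            differential.fit_site_models(pb, adjust=None)

    def test_fdr_monotone_in_p(self):
        pb = make_null_pseudobulk(5, n_sites=100)
        res = differential.fit_site_models(pb)
        res = res.dropna(subset=["p"]).sort_values("p")
        assert (np.diff(res["fdr"].to_numpy()) >= -1e-12).all()

    def test_concordant_with_beta_binomial_lrt_oracle(self):
        # small instances: 6 samples, 2 groups, no adjustment
        rng = np.random.default_rng(123)
        shifts = {i: s for i, s in enumerate(
            rng.uniform(0, 1.2, size=40) * rng.integers(0, 2, size=40)
        )}
        pb = make_null_pseudobulk(
            99, n_sites=40, n_regions=1, reps_per_cell=3, planted=shifts
        )
        res = differential.fit_site_models(pb, adjust=None)
        arm = (pb.samples["phenotype"] == "inhibitory").to_numpy()
        oracle_p = np.array([
            _bb_lrt_pvalue(
                pb.edited[i], pb.edited[i] + pb.unedited[i], arm
            )
            for i in range(40)
        ])
        rho = stats.spearmanr(res["p"].to_numpy(), oracle_p).statistic
        assert rho >= 0.95


def _bb_loglik(params, k, n):
    """Beta-binomial log-likelihood with mean p and correlation rho."""
    logit_p, logit_rho = params
    p = 1 / (1 + np.exp(-logit_p))
    rho = 1 / (1 + np.exp(-logit_rho)) * 0.99 + 1e-6
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    return float(stats.betabinom.logpmf(k, n, a, b).sum())


def _bb_lrt_pvalue(k, n, arm):
    """Exact-model oracle: beta-binomial LRT of equal group means."""

    def nll_null(params):
        return -_bb_loglik(params, k, n)

    def nll_alt(params):
        la, lb, lr = params
        return -(
            _bb_loglik((la, lr), k[~arm], n[~arm])
            + _bb_loglik((lb, lr), k[arm], n[arm])
        )

    p0 = np.clip(k.sum() / n.sum(), 1e-4, 1 - 1e-4)
    x0 = np.log(p0 / (1 - p0))
    null = optimize.minimize(
        nll_null, [x0, -3.0], method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
    )
    alt = optimize.minimize(
        nll_alt, [x0, x0, -3.0], method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000},
    )
    lrt = max(0.0, 2 * (null.fun - alt.fun))
    return float(stats.chi2.sf(lrt, 1))


class TestGeneDirectionalTest:
    def test_flat_gene_has_p_near_one(self):
        pheno = ["excitatory"] * 4 + ["inhibitory"] * 4
        counts = np.full((3, 8), 30)
        pb = _pb(counts, counts, pheno)
        res = differential.gene_directional_test(
            pb, adjust=None, n_perm=500, seed=0
        )
        assert res["p"].iloc[0] > 0.9

    def test_low_n_perm_rejected(self):
        pb = make_null_pseudobulk(1, n_sites=8)
        with pytest.raises(ValueError, match="n_perm"):
            differential.gene_directional_test(pb, n_perm=50)

    def test_min_sites_excludes_small_genes(self):
        pb = make_null_pseudobulk(1, n_sites=9)
        pb.sites["gene_id"] = ["gA"] * 8 + ["gB"]
        res = differential.gene_directional_test(pb, n_perm=200, seed=1)
        assert list(res["gene_id"]) == ["gA"]

    def test_pvalue_invariant_to_site_order(self):
        pb = make_null_pseudobulk(17, n_sites=24)
        res1 = differential.gene_directional_test(pb, n_perm=1000, seed=5)
        order = np.random.default_rng(0).permutation(24)
        pb2 = PseudobulkTable(
            edited=pb.edited[order],
            unedited=pb.unedited[order],
            samples=pb.samples,
            sites=pb.sites.iloc[order].reset_index(drop=True),
        )
        res2 = differential.gene_directional_test(pb2, n_perm=1000, seed=5)
        merged = res1.merge(res2, on="gene_id", suffixes=("_1", "_2"))
        assert np.allclose(merged["stat_1"], merged["stat_2"])
        assert np.allclose(merged["p_1"], merged["p_2"])

    def test_planted_gene_detected_with_direction(self):
        planted = {i: 0.8 for i in range(10)}
        pb = make_null_pseudobulk(4, n_sites=50, planted=planted)
        pb.sites["gene_id"] = ["hot"] * 10 + [
            f"g{i // 4}" for i in range(40)
        ]
        res = differential.gene_directional_test(pb, n_perm=2000, seed=2)
        hot = res[res["gene_id"] == "hot"].iloc[0]
        assert hot["direction"] == "up"  # inhibitory = second level
        assert hot["fdr"] < 0.1


class TestDiseaseOverlap:
    def _sites(self, a, b, c, d):
        # a/b: disease sites in/out of biased genes; c/d: non-disease
        return pd.DataFrame(
            {
                "gene_id": (
                    ["in"] * a + ["out"] * b + ["in"] * c + ["out"] * d
                ),
                "disease": [True] * (a + b) + [False] * (c + d),
            }
        )

    def test_symmetric_table_is_null(self):
        sites = self._sites(10, 90, 10, 90)
        res = differential.disease_overlap_test(sites, "disease", {"in"})
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        sites = self._sites(8, 2, 2, 8)
        res = differential.disease_overlap_test(sites, "disease", {"in"})
        # exhaustive enumeration: tables with fixed margins, two-sided by
        # summing probabilities <= observed
        total, row1, col1 = 20, 10, 10
        obs_p = stats.hypergeom.pmf(8, total, row1, col1)
        p_exact = sum(
            stats.hypergeom.pmf(x, total, row1, col1)
            for x in range(max(0, row1 + col1 - total), min(row1, col1) + 1)
            if stats.hypergeom.pmf(x, total, row1, col1) <= obs_p + 1e-12
        )
        assert res["p"] == pytest.approx(p_exact, rel=1e-6)
        assert res["odds_ratio"] == pytest.approx((8 * 8) / (2 * 2))

    def test_empty_margin_flagged_degenerate(self):
        sites = self._sites(0, 0, 10, 90)
        res = differential.disease_overlap_test(sites, "disease", {"in"})
        assert res["degenerate"]
        assert res["p"] == 1.0
        assert np.isnan(res["odds_ratio"])


class TestInclusionExclusionSanity:
    def test_all_label_splits_enumerable(self):
        # guard: the 8-sample design admits 70 phenotype splits, which is
        # why the gene null must come from rotations, not label permutation
        n = len(list(itertools.combinations(range(8), 4)))
        assert n == 70
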