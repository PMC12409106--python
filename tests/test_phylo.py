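"""Phylogenetic signal and comparative regression: frozen independent-oracle
values for K and PGLS, calibration simulations, star-tree identities."""

import numpy as np
import pandas as pd
import pytest

from spectraits.phylo import (blomberg_k, k_significance, pearson_trait_env,
                              pgls_fit, phylo_vcv, population_means,
                              read_tree, spectral_k_profile)
from spectraits.simulate import gen_bm_traits, gen_phylogeny
from spectraits.spectra import SpectraSet

from conftest import star_tree


def oracle_tipdata():
    """8-tip tree + two BM traits; K and PGLS values frozen from independent
    comparative-methods implementations."""
    tree = gen_phylogeny(8, seed=11)
    y = gen_bm_traits(tree, 1.0, 0.0, seed=5).iloc[:, 0].round(6)
    x = gen_bm_traits(tree, 1.0, 0.0, seed=9).iloc[:, 0].round(6)
    return tree, y, x


class TestVcv:
    def test_diagonal_is_depth_offdiag_is_mrca_depth(self, balanced4):
        V = phylo_vcv(balanced4)
        assert np.allclose(np.diag(V), 2.0)
        assert V.loc["a", "b"] == 1.0
        assert V.loc["a", "c"] == 0.0

    def test_star_tree_identity_scaled(self):
        V = phylo_vcv(star_tree(5, depth=3.0))
        assert np.allclose(V.to_numpy(), 3.0 * np.eye(5))


class TestPopulationMeans:
    def test_identity_single_sample_per_tip(self):
        traits = pd.DataFrame({"t": [1.0, 2.0]}, index=["s1", "s2"])
        out = population_means(traits, {"s1": "a", "s2": "b"})
        assert out.loc["a", "t"] == 1.0
        assert (out["n"] == 1).all()

    def test_mean_and_se(self):
        traits = pd.DataFrame({"t": [2.0, 4.0, 5.0]}, index=["s1", "s2", "s3"])
        out = population_means(traits, {"s1": "a", "s2": "a", "s3": "b"})
        assert out.loc["a", "t"] == 3.0
        sd = np.std([2.0, 4.0], ddof=1)
        assert np.isclose(out.loc["a", "se_t"], sd / np.sqrt(2))

    def test_unmapped_tip_rejected(self):
        traits = pd.DataFrame({"t": [1.0]}, index=["s1"])
        with pytest.raises(KeyError):
            population_means(traits, {"s1": "a", "ghost": "b"})


class TestBlombergK:
    def test_frozen_oracle_value(self):
        tree, y, _ = oracle_tipdata()
        assert np.isclose(blomberg_k(tree, y), 0.319317, atol=1e-5)

    def test_affine_invariance(self):
        tree, y, _ = oracle_tipdata()
        k0 = blomberg_k(tree, y)
        assert np.isclose(blomberg_k(tree, 3.0 * y + 7.0), k0, atol=1e-10)

    def test_constant_trait_rejected(self):
        tree, y, _ = oracle_tipdata()
        with pytest.raises(ValueError):
            blomberg_k(tree, y * 0 + 1.0)

    def test_bm_calibration_near_one(self):
        tree = gen_phylogeny(50, seed=2)
        ks = [blomberg_k(tree, gen_bm_traits(tree, 1.0, 0.0,
                                             seed=s).iloc[:, 0])
              for s in range(100)]
        assert 0.85 < np.mean(ks) < 1.15

    def test_white_noise_low_k(self):
        tree = gen_phylogeny(50, seed=2)
        rng = np.random.default_rng(0)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        ks = [blomberg_k(tree, pd.Series(rng.standard_normal(50), index=tips))
              for _ in range(50)]
        assert np.mean(ks) < 0.5


class TestKSignificance:
    def test_bm_trait_detected(self):
        tree = gen_phylogeny(30, seed=4)
        y = gen_bm_traits(tree, 1.0, 0.0, seed=3).iloc[:, 0]
        r = k_significance(tree, y, n_perm=199, n_sim=199, seed=0)
        assert r.p_wn <= 0.05
        assert r.bm_low <= r.bm_high

    def test_permuted_trait_not_detected(self):
        tree = gen_phylogeny(30, seed=4)
        y = gen_bm_traits(tree, 1.0, 0.0, seed=3).iloc[:, 0]
        rng = np.random.default_rng(8)
        yp = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        r = k_significance(tree, yp, n_perm=199, n_sim=99, seed=0)
        assert r.p_wn > 0.05

    def test_deterministic_given_seed(self):
        tree, y, _ = oracle_tipdata()
        r1 = k_significance(tree, y, n_perm=99, n_sim=99, seed=7)
        r2 = k_significance(tree, y, n_perm=99, n_sim=99, seed=7)
        assert (r1.p_wn, r1.bm_low, r1.bm_high) == (r2.p_wn, r2.bm_low,
                                                    r2.bm_high)


class TestSpectralProfile:
    def _profile_inputs(self, seed=0):
        tree = gen_phylogeny(12, seed=seed)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        bm = gen_bm_traits(tree, 1.0, 0.0, seed=seed).iloc[:, 0]
        rng = np.random.default_rng(seed)
        w = np.array([450.0, 500.0, 550.0, 1500.0, 1600.0, 1700.0])
        vis = np.outer(bm.to_numpy(), [1.0, 0.8, 0.6])
        swir = rng.standard_normal((12, 3))
        values = np.hstack([vis, swir]) * 0.01 + 0.5
        s = SpectraSet(w, values, state="resampled", sample_ids=tuple(tips))
        return tree, s, {t: t for t in tips}

    def test_profile_bookkeeping_and_regions(self):
        tree, s, mapping = self._profile_inputs()
        prof = spectral_k_profile(tree, s, mapping, n_perm=49, n_sim=49,
                                  seed=0)
        assert len(prof) == 6
        assert list(prof["region"].iloc[:3]) == ["VIS"] * 3
        assert list(prof["region"].iloc[3:]) == ["SWIR"] * 3

    def test_constant_band_skipped(self):
        tree, s, mapping = self._profile_inputs()
        vals = s.values.copy()
        vals[:, 0] = 0.5
        s2 = SpectraSet(s.wavelengths, vals, state="resampled",
                        sample_ids=s.sample_ids)
        prof = spectral_k_profile(tree, s2, mapping, n_perm=19, n_sim=19,
                                  seed=0)
        assert prof["constant"].iloc[0]
        assert np.isnan(prof["k"].iloc[0])

    def test_bm_bands_score_higher_than_noise_bands(self):
        wins = 0
        for seed in range(5):
            tree, s, mapping = self._profile_inputs(seed=seed)
            prof = spectral_k_profile(tree, s, mapping, n_perm=19, n_sim=19,
                                      seed=seed)
            wins += (prof["k"].iloc[:3].median() > prof["k"].iloc[3:].median())
        assert wins >= 4


class TestPgls:
    def test_star_tree_equals_ols(self):
        tree = star_tree(12, depth=2.0)
        rng = np.random.default_rng(0)
        tips = [f"x{i}" for i in range(12)]
        x = pd.Series(rng.normal(size=12), index=tips)
        y = pd.Series(1.2 * x + rng.normal(0, 0.3, 12), index=tips)
        r = pgls_fit(tree, y, x)
        slope, intercept = np.polyfit(x.to_numpy(), y.to_numpy(), 1)
        assert np.isclose(r.slope, slope, atol=1e-9)
        assert np.isclose(r.intercept, intercept, atol=1e-9)

    def test_exact_linear_relation(self):
        tree, _, x = oracle_tipdata()
        y = 2.0 * x
        r = pgls_fit(tree, y, x)
        assert np.isclose(r.slope, 2.0, atol=1e-9)
        assert r.sigma2 < 1e-18

    def test_frozen_oracle_values(self):
        tree, y, x = oracle_tipdata()
        r = pgls_fit(tree, y, x)
        assert np.isclose(r.slope, -0.15749554, atol=1e-6)
        assert np.isclose(r.slope_se, 0.27750442, atol=1e-6)
        assert np.isclose(r.p_value, 0.59093288, atol=1e-6)
        assert r.n == 8

    def test_slope_recovery_under_bm_errors(self):
        tree = gen_phylogeny(50, seed=6)
        slopes = []
        for s in range(60):
            x = gen_bm_traits(tree, 1.0, 0.0, seed=2000 + s).iloc[:, 0]
            noise = gen_bm_traits(tree, 0.25, 0.0, seed=5000 + s).iloc[:, 0]
            y = 1.5 * x + noise
            slopes.append(pgls_fit(tree, y, x).slope)
        assert abs(np.mean(slopes) - 1.5) < 0.1

    def test_too_few_tips_rejected(self):
        tree = star_tree(3)
        tips = [f"x{i}" for i in range(3)]
        with pytest.raises(ValueError):
            pgls_fit(tree, pd.Series([1.0, 2, 3], index=tips),
                     pd.Series([1.0, 2, 4], index=tips))


class TestPearson:
    def test_perfect_correlation(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4]}, index=list("wxyz"))
        out = pearson_trait_env(t, t.rename(columns={"a": "b"}))
        assert np.isclose(out["r"].iloc[0], 1.0)

    def test_constructed_orthogonal(self):
        t = pd.DataFrame({"a": [-1.0, 0, 1, 0]}, index=list("wxyz"))
        e = pd.DataFrame({"b": [0.0, -1, 0, 1]}, index=list("wxyz"))
        out = pearson_trait_env(t, e)
        assert abs(out["r"].iloc[0]) < 1e-12

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(20)]
        t = pd.DataFrame({"a": rng.normal(size=20)}, index=idx)
        e = pd.DataFrame({"b": rng.normal(size=20)}, index=idx)
        out = pearson_trait_env(t, e)
        a, b = t["a"].to_numpy(), e["b"].to_numpy()
        r_manual = (((a - a.mean()) * (b - b.mean())).sum()
                    / np.sqrt(((a - a.mean())**2).sum()
                              * ((b - b.mean())**2).sum()))
        assert np.isclose(out["r"].iloc[0], r_manual, atol=1e-12)

    def test_zero_variance_rejected(self):
        t = pd.DataFrame({"a": [1.0, 1, 1, 1]}, index=list("wxyz"))
        e = pd.DataFrame({"b": [1.0, 2, 3, 4]}, index=list("wxyz"))
        with pytest.raises(ValueError):
            pearson_trait_env(t, e)


class TestTreeIO:
    def test_newick_roundtrip(self, tmp_path):
        tree = gen_phylogeny(7, seed=1)
        p = tmp_path / "t.nwk"
        tree.write(path=str(p), schema="newick")
        back = read_tree(p)
        assert len(back.leaf_nodes()) == 7
        assert np.allclose(np.diag(phylo_vcv(back)),
                           np.diag(phylo_vcv(tree)), atol=1e-6)

    def test_newick_string_accepted(self):
        t = read_tree("((a:1,b:1):1,(c:1,d:1):1);")
        assert len(t.leaf_nodes()) == 4
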