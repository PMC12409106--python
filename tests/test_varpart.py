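"""RDA and variance partitioning: collinearity filters against brute-force
oracles, R2 identities, partitioning closure, frozen independent-oracle
values, permutation behaviour."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from spectraits.varpart import (corr_filter, partial_rda, rda,
                                spatial_predictors, variance_partition,
                                varpart_table, vif_filter, _vif)


class TestVifFilter:
    def test_orthogonal_variables_kept(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(50, 4))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        env = pd.DataFrame(Q, columns=list("abcd"))
        out = vif_filter(env, threshold=5.0)
        assert list(out.columns) == list("abcd")
        assert np.allclose(_vif(Q), 1.0)

    def test_duplicated_variable_dropped_once(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        env = pd.DataFrame({"a": x, "b": rng.normal(size=60), "a2": x})
        out = vif_filter(env, threshold=5.0)
        assert sorted(out.columns) in (["a", "b"], ["a2", "b"])
        assert len(out.columns) == 2

    def test_survivors_match_bruteforce_all_subsets(self):
        """Iterative deletion lands on a maximal subset with all VIF below
        threshold (checked against exhaustive enumeration)."""
        rng = np.random.default_rng(2)
        n = 200
        a = rng.normal(size=n)
        b = 0.95 * a + np.sqrt(1 - 0.95**2) * rng.normal(size=n)
        c = rng.normal(size=n)
        env = pd.DataFrame({"a": a, "b": b, "c": c})
        out = vif_filter(env, threshold=5.0)
        valid = []
        for k in (3, 2):
            for cols in itertools.combinations(env.columns, k):
                if (_vif(env[list(cols)].to_numpy()) < 5.0).all():
                    valid.append(set(cols))
            if valid:
                break
        assert set(out.columns) in valid

    def test_insufficient_data_rejected(self):
        env = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4)))
        with pytest.raises(ValueError):
            vif_filter(env)


class TestCorrFilter:
    def test_low_correlation_identity(self):
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(80, 4)))
        env = pd.DataFrame(Q, columns=list("abcd"))
        assert list(corr_filter(env, 0.6).columns) == list("abcd")

    def test_perfect_correlation_second_dropped(self):
        x = np.arange(20.0)
        env = pd.DataFrame({"a": x, "b": 2 * x + 1})
        assert list(corr_filter(env, 0.6).columns) == ["a"]

    def test_order_dependence_documented(self):
        """Greedy retention can keep different survivors under reversed
        input order; both outcomes satisfy the pairwise constraint."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        y = 0.7 * x + np.sqrt(1 - 0.49) * rng.normal(size=300)
        z = 0.7 * y + np.sqrt(1 - 0.49) * rng.normal(size=300)
        env = pd.DataFrame({"x": x, "y": y, "z": z})
        fwd = corr_filter(env, 0.6)
        rev = corr_filter(env[["z", "y", "x"]], 0.6)
        for out in (fwd, rev):
            c = out.corr().abs().to_numpy()
            assert (c[np.triu_indices_from(c, 1)] <= 0.6).all()


class TestRda:
    def test_exact_linear_response_r2_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        B = rng.normal(size=(3, 2))
        out = rda(X @ B, X)
        assert np.isclose(out["r2"], 1.0)

    def test_univariate_equals_squared_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        out = rda(y, x)
        r = np.corrcoef(x, y)[0, 1]
        assert np.isclose(out["r2"], r**2, atol=1e-9)

    def test_orthogonal_predictors_adjusted_r2_near_zero(self):
        rng = np.random.default_rng(2)
        vals = [rda(rng.normal(size=(60, 2)),
                    rng.normal(size=(60, 3)))["adj_r2"] for _ in range(100)]
        assert abs(np.mean(vals)) < 0.02

    def test_rank_deficient_warns(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        X = np.column_stack([x, 2 * x])
        with pytest.warns(UserWarning):
            rda(rng.normal(size=30), X)


class TestPartialRda:
    def test_empty_conditioning_equals_rda(self):
        rng = np.random.default_rng(0)
        Y, X = rng.normal(size=(40, 2)), rng.normal(size=(40, 2))
        assert np.isclose(partial_rda(Y, X)["semipartial_adj_r2"],
                          rda(Y, X)["adj_r2"])

    def test_orthogonal_blocks_semipartial_equals_marginal(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(100, 4))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        X, Z = Q[:, :2], Q[:, 2:]
        Y = X @ rng.normal(size=(2, 2)) + 0.5 * rng.normal(size=(100, 2))
        # with orthogonal blocks the variance X adds on top of Z equals the
        # variance X explains alone
        out = partial_rda(Y, X, Z)
        assert np.isclose(out["r2_increment"], rda(Y, X)["r2"], atol=1e-6)

    def test_generative_shares_recovered(self):
        rng = np.random.default_rng(2)
        n = 300
        E = rng.normal(size=n)
        G = rng.normal(size=n)
        noise = rng.normal(size=n)
        Y = 1.0 * E + 0.5 * G + noise
        var_tot = 1.0 + 0.25 + 1.0
        share_e = 1.0 / var_tot
        share_g = 0.25 / var_tot
        a = partial_rda(Y, E, G)["semipartial_adj_r2"]
        c = partial_rda(Y, G, E)["semipartial_adj_r2"]
        assert abs(a - share_e) < 0.05
        assert abs(c - share_g) < 0.05

    def test_x_inside_span_of_z_warns_zero(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(50, 2))
        with pytest.warns(UserWarning):
            out = partial_rda(rng.normal(size=50), z[:, :1], z)
        assert out["semipartial_adj_r2"] == 0.0


def oracle_fixture():
    """Deterministic 12-sample fixture; expected fractions frozen from an
    independent constrained-ordination implementation."""
    rng = np.random.default_rng(42)
    n = 12
    Y = rng.normal(size=(n, 2)).round(4)
    E = rng.normal(size=(n, 2)).round(4)
    G = rng.normal(size=(n, 2)).round(4)
    Y[:, 0] += E[:, 0] * 0.8 + G[:, 0] * 0.5
    return Y, pd.DataFrame(E, columns=["e1", "e2"]), \
        pd.DataFrame(G, columns=["g1", "g2"])


class TestVariancePartition:
    def test_frozen_oracle_fractions(self):
        Y, E, G = oracle_fixture()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = variance_partition(Y, E, G, n_perm=0)
        assert np.isclose(res.total_adj_r2, 0.064778, atol=1e-6)
        assert np.isclose(res.env_given_geo, 0.058040, atol=1e-6)
        assert np.isclose(res.geo_given_env, 0.049043, atol=1e-6)
        assert np.isclose(res.joint, -0.042305, atol=1e-6)
        assert np.isclose(res.unexplained, 0.935222, atol=1e-6)

    def test_closure(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(80, 3))
        E = pd.DataFrame(rng.normal(size=(80, 2)), columns=["e1", "e2"])
        G = pd.DataFrame(rng.normal(size=(80, 2)), columns=["g1", "g2"])
        res = variance_partition(Y, E, G, n_perm=0)
        total = res.env_given_geo + res.geo_given_env + res.joint
        assert abs(total - res.total_adj_r2) < 1e-6
        assert abs(res.unexplained - (1 - res.total_adj_r2)) < 1e-6

    def test_duplicated_blocks_all_joint(self):
        rng = np.random.default_rng(2)
        E = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
        Y = E.to_numpy() @ rng.normal(size=(2, 2)) + \
            0.3 * rng.normal(size=(60, 2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = variance_partition(Y, E, E.copy(), n_perm=0)
        assert abs(res.env_given_geo) < 1e-9
        assert abs(res.geo_given_env) < 1e-9
        assert res.joint > 0.3

    def test_ibe_dominant_data_a_exceeds_c(self):
        from spectraits.simulate import (SimConfig, gen_env_geo,
                                         gen_ibe_ibd_response)
        wins = 0
        reps = 15
        for seed in range(reps):
            groups = pd.Series(np.repeat([f"g{i}" for i in range(20)], 10),
                               index=range(200))
            cfg = SimConfig(ibe_fraction=0.4, ibd_fraction=0.1,
                            seed=900 + seed)
            env, geo, truth = gen_env_geo(cfg, groups)
            Y = gen_ibe_ibd_response(cfg, truth)
            res = variance_partition(
                Y.to_numpy(), truth["group_components"].iloc[:, [0]],
                geo[["latitude", "longitude"]], n_perm=0)
            wins += res.env_given_geo > res.geo_given_env
        assert wins / reps >= 0.95

    def test_permutation_p_small_for_real_effect(self):
        rng = np.random.default_rng(4)
        E = pd.DataFrame({"e": rng.normal(size=80)})
        G = pd.DataFrame({"g": rng.normal(size=80)})
        Y = 1.0 * E["e"].to_numpy() + 0.3 * rng.normal(size=80)
        res = variance_partition(Y, E, G, n_perm=199, seed=0)
        assert res.p_values["env_given_geo"] < 0.05
        assert res.p_values["geo_given_env"] > 0.05

    def test_table_flags(self):
        Y, E, G = oracle_fixture()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = variance_partition(Y, E, G, n_perm=49, seed=1)
        tbl = varpart_table([res])
        assert set(tbl["fraction"]) == {"IBE", "IBD", "joint"}
        assert tbl["not_significant"].dtype == bool

    def test_spatial_predictor_block_shape(self):
        geo = pd.DataFrame({"latitude": [0.0, 1, 2, 3],
                            "longitude": [2.0, 1, 0, 2]})
        sp = spatial_predictors(geo)
        assert list(sp.columns) == ["lon", "lat", "lon2", "lat2", "lon_lat"]
        assert np.allclose(sp[["lon", "lat"]].mean(), 0.0)
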