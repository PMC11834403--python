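"""Bray-Curtis identities, month-lag binning arithmetic, permutation-test
exactness against brute-force enumeration, and the PC1-distance regression."""

import numpy as np
import pandas as pd
import pytest
from skbio.stats.distance import DistanceMatrix as SkDM
from skbio.stats.distance import anosim as sk_anosim
from skbio.stats.distance import mantel as sk_mantel

import protnet as pn
from protnet.containers import EnvTable
from oracles import brute_force_anosim, brute_force_mantel_p


def _df(rows):
    x = np.asarray(rows, dtype=float)
    return pd.DataFrame(x, index=[f"s{i}" for i in range(len(x))])


class TestBrayCurtis:
    def test_identical_rows_distance_zero(self):
        d = pn.bray_curtis(_df([[1, 2, 3], [1, 2, 3]]))
        assert d.data[0, 1] == 0.0

    def test_disjoint_support_distance_one(self):
        d = pn.bray_curtis(_df([[1, 0, 2], [0, 3, 0]]))
        assert d.data[0, 1] == 1.0

    def test_hand_example(self):
        d = pn.bray_curtis(_df([[1, 2, 3], [3, 2, 1]]))
        assert d.data[0, 1] == pytest.approx(1 / 3, abs=1e-12)

    def test_bounds_and_symmetry(self, rng):
        d = pn.bray_curtis(_df(rng.random((12, 5))))
        assert (d.data >= 0).all() and (d.data <= 1).all()
        assert np.allclose(d.data, d.data.T)
        np.testing.assert_allclose(np.diag(d.data), 0)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            pn.bray_curtis(_df([[1, 2], [0, 0]]))


class TestLagProfile:
    def test_day_to_month_conversion(self):
        assert pn.month_lag(365) == pytest.approx(12.0066, abs=1e-4)

    def test_binning_fixture(self):
        # days 0, 30, 365 -> pair lags 0.987, 11.020, 12.007 -> bins 1, 11, 12
        dates = pd.Series(pd.to_datetime(["2010-01-01", "2010-01-31",
                                          "2011-01-01"]),
                          index=["s0", "s1", "s2"])
        d = pn.bray_curtis(_df([[1, 2], [2, 1], [1, 1]]))
        prof = pn.lag_profile(d, dates)
        assert sorted(prof.table["lag_months"]) == [1, 11, 12]
        assert prof.table["n_pairs"].sum() == 3

    def test_zero_lag_pairs_excluded_and_counts_conserved(self, rng):
        dates = pd.Series(pd.to_datetime(
            ["2010-01-01", "2010-01-01", "2010-03-01", "2010-07-01"]),
            index=[f"s{i}" for i in range(4)])
        d = pn.bray_curtis(_df(rng.random((4, 3))))
        prof = pn.lag_profile(d, dates)
        assert prof.n_pairs_excluded == 1
        assert prof.table["n_pairs"].sum() == 6 - 1

    def test_seasonal_community_similarity_12_exceeds_6(self):
        cfg = pn.SyntheticConfig(
            n_asvs=25, n_months=120, missing_month_fraction=0.1,
            seasonal_fraction=1.0, seasonal_amplitude=2.0, drift_sd=0.0,
            n_planted_edges=0, seed=0)
        table, _, _ = pn.generate_community(cfg)
        rel = table.counts.div(table.counts.sum(axis=1), axis=0)
        t = pn.lag_profile(pn.bray_curtis(rel), table.dates)\
              .table.set_index("lag_months")
        assert t.loc[12, "mean_sim"] > t.loc[6, "mean_sim"]


class TestMantel:
    def test_self_comparison(self, rng):
        d = pn.bray_curtis(_df(rng.random((7, 4))))
        m = pn.mantel_test(d, d, n_perm=99, seed=1)
        assert m.r == pytest.approx(1.0)
        assert m.p == pytest.approx(1 / 100)

    def test_exact_enumeration_matches_brute_force(self, rng):
        x, y = rng.random((4, 3)), rng.random((4, 3))
        d1, d2 = pn.bray_curtis(_df(x)), pn.bray_curtis(_df(y))
        m = pn.mantel_test(d1, d2, exact=True)
        r_bf, p_bf = brute_force_mantel_p(d1.data, d2.data)
        assert m.r == pytest.approx(r_bf, abs=1e-12)
        assert m.p == pytest.approx(p_bf, abs=1e-12)

    def test_statistic_agrees_with_skbio(self, rng):
        x, y = rng.random((9, 4)), rng.random((9, 4))
        d1, d2 = pn.bray_curtis(_df(x)), pn.bray_curtis(_df(y))
        m = pn.mantel_test(d1, d2, n_perm=49, seed=3)
        r_sk = sk_mantel(SkDM(d1.data, d1.ids), SkDM(d2.data, d2.ids),
                         method="spearman", permutations=0,
                         alternative="greater")[0]
        assert m.r == pytest.approx(r_sk, abs=1e-12)

    def test_constant_matrix_rejected(self):
        ids = ["s0", "s1", "s2"]
        flat = pn.DistanceMatrix(np.array([[0, .5, .5], [.5, 0, .5],
                                           [.5, .5, 0]]), ids)
        d = pn.bray_curtis(_df([[1, 2], [2, 1], [3, 1]]))
        with pytest.raises(ValueError, match="constant"):
            pn.mantel_test(d, flat, n_perm=9)

    def test_seeded_runs_reproducible(self, rng):
        x, y = rng.random((10, 4)), rng.random((10, 4))
        d1, d2 = pn.bray_curtis(_df(x)), pn.bray_curtis(_df(y))
        a = pn.mantel_test(d1, d2, n_perm=199, seed=5)
        b = pn.mantel_test(d1, d2, n_perm=199, seed=5)
        assert a.p == b.p and a.r == b.r


class TestAnosim:
    def test_perfect_separation_R_is_one(self):
        D = np.full((6, 6), 0.9)
        D[:3, :3] = 0.1
        D[3:, 3:] = 0.1
        np.fill_diagonal(D, 0)
        dm = pn.DistanceMatrix(D, [f"s{i}" for i in range(6)])
        res = pn.anosim(dm, ["a"] * 3 + ["b"] * 3, exact=True)
        assert res.R == pytest.approx(1.0)

    def test_exact_enumeration_matches_brute_force(self, rng):
        d = pn.bray_curtis(_df(rng.random((6, 4))))
        groups = ["a", "a", "a", "b", "b", "b"]
        res = pn.anosim(d, groups, exact=True)
        R_bf, p_bf = brute_force_anosim(d.data, groups)
        assert res.R == pytest.approx(R_bf, abs=1e-12)
        assert res.p == pytest.approx(p_bf, abs=1e-12)

    def test_statistic_agrees_with_skbio(self, rng):
        d = pn.bray_curtis(_df(rng.random((10, 5))))
        groups = ["a"] * 5 + ["b"] * 5
        res = pn.anosim(d, groups, n_perm=49, seed=2)
        sk = sk_anosim(SkDM(d.data, d.ids), grouping=groups, permutations=0)
        assert res.R == pytest.approx(sk["test statistic"], abs=1e-12)

    def test_null_R_centered_near_zero(self, rng):
        d = pn.bray_curtis(_df(rng.random((12, 5))))
        Rs = [pn.anosim(d, rng.permutation(["a"] * 6 + ["b"] * 6),
                        n_perm=9, seed=s).R for s in range(30)]
        assert abs(np.mean(Rs)) < 0.15

    def test_single_group_rejected(self, rng):
        d = pn.bray_curtis(_df(rng.random((4, 3))))
        with pytest.raises(ValueError):
            pn.anosim(d, ["a"] * 4, n_perm=9)


class TestPc1Regression:
    def test_constructed_linear_dependence(self, rng):
        n = 10
        env = pd.DataFrame({
            "v": np.linspace(-2, 2, n),
            "w": rng.normal(0, 1e-8, n),  # negligible second axis
        }, index=[f"s{i}" for i in range(n)])
        pc1 = env["v"].to_numpy() - env["v"].mean()  # PC1 ~ v exactly
        iu = np.triu_indices(n, k=1)
        dpc1 = np.abs(pc1[iu[0]] - pc1[iu[1]])
        sim = 0.8 - 0.1 * dpc1
        D = np.zeros((n, n))
        D[iu] = 1 - sim
        D = D + D.T
        dm = pn.DistanceMatrix(D, list(env.index))
        res = pn.pc1_distance_regression(EnvTable(env, standardized=True), dm)
        assert res.slope < 0
        assert res.r2 == pytest.approx(1.0, abs=1e-6)
        assert res.pc1_variance_ratio > 0.99

    def test_matches_normal_equations(self, rng):
        n = 6
        env = pd.DataFrame(rng.standard_normal((n, 3)),
                           index=[f"s{i}" for i in range(n)])
        env.columns = ["a", "b", "c"]
        env = (env - env.mean()) / env.std(ddof=1)
        d = pn.bray_curtis(_df(rng.random((n, 4))))
        res = pn.pc1_distance_regression(EnvTable(env, standardized=True), d)
        # independent least squares via the normal equations
        from sklearn.decomposition import PCA
        pca = PCA().fit(env.to_numpy())
        load = pca.components_[0]
        pc1 = env.to_numpy() @ load * np.sign(load[np.argmax(np.abs(load))])
        iu = np.triu_indices(n, k=1)
        x = np.abs(pc1[iu[0]] - pc1[iu[1]])
        y = 1 - d.data[iu]
        A = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)

    def test_single_variable_env_rejected(self, rng):
        env = pd.DataFrame({"v": rng.random(5)},
                           index=[f"s{i}" for i in range(5)])
        d = pn.bray_curtis(_df(rng.random((5, 3))))
        with pytest.raises(ValueError, match="at least 2"):
            pn.pc1_distance_regression(EnvTable(env, standardized=True), d)
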