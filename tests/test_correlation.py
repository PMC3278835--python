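"""Correlation: Spearman with t-transform, R^2, jackknife, factor analysis."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphodyn.correlation import (
    CovarianceFactorAnalysis,
    factor_analysis,
    jackknife_correlation,
    multiple_correlation,
    spearman_with_p,
    time_average_edge,
)
from morphodyn.edge import EdgePrint


def make_table(n=50, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    return pd.DataFrame(
        {
            "speed_um_per_h": x,
            "persistence_h": 0.5 * x + rng.normal(0, 0.5, n),
            "chemotactic_index": rng.normal(size=n),
            "ProVL_um_per_min": x**3 + rng.normal(0, 0.1, n),
            "RetVL_um_per_min": rng.normal(size=n),
        }
    )


class TestTimeAverageEdge:
    def test_zero_print(self):
        ep = EdgePrint(np.zeros(11), np.zeros(11), 10.0)
        assert time_average_edge(ep) == (0.0, 0.0)

    def test_constant_print(self):
        ep = EdgePrint(np.full(11, 0.7), np.linspace(0, 1, 11), 10.0)
        provl, retvl = time_average_edge(ep)
        assert np.isclose(provl, 0.7)
        assert np.isclose(retvl, np.mean(np.linspace(0, 1, 11)))


class TestSpearman:
    def test_monotone_transform_gives_rho_one(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.exp(np.arange(10.0))})
        rep = spearman_with_p(df)
        assert np.isclose(rep.rho.loc["a", "b"], 1.0)
        assert rep.p_values.loc["a", "b"] == 0.0

    def test_matches_scipy_spearmanr(self):
        df = make_table()
        rep = spearman_with_p(df)
        ref_rho, ref_p = stats.spearmanr(df.to_numpy())
        assert np.allclose(rep.rho.to_numpy(), ref_rho, atol=1e-12)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(rep.p_values.to_numpy()[off], ref_p[off], atol=1e-10)

    def test_t_transform_close_to_exact_permutation_p(self):
        """Exhaustive oracle at N=8: all 8! rank permutations."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=8)
        y = 0.8 * x + rng.normal(0, 0.6, 8)
        rep = spearman_with_p(pd.DataFrame({"x": x, "y": y}))
        rho_obs = rep.rho.loc["x", "y"]
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        perms = np.array(list(permutations(ry)))  # (40320, 8)
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        rhos = (pc @ rxc) / np.sqrt((pc**2).sum(axis=1) * (rxc**2).sum())
        p_exact = np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12)
        assert abs(rep.p_values.loc["x", "y"] - p_exact) <= 0.02

    def test_type_one_error_rate(self):
        """Independent features: raw-alpha flag rate ~ 5%."""
        rng = np.random.default_rng(5)
        flags = []
        for _ in range(500):
            df = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
            flags.append(bool(spearman_with_p(df).significant.loc["a", "b"]))
        assert 0.025 <= np.mean(flags) <= 0.08

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            spearman_with_p(make_table(n=3))


class TestMultipleCorrelation:
    def test_exact_linear_relation_r2_one(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=(2, 40))
        df = pd.DataFrame({"speed_um_per_h": 2 * a - b, "a": a, "b": b})
        assert np.isclose(multiple_correlation(df), 1.0)

    def test_single_predictor_equals_squared_pearson(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=60)
        y = a + rng.normal(0, 1, 60)
        df = pd.DataFrame({"speed_um_per_h": y, "a": a})
        r = stats.pearsonr(y, a).statistic
        assert np.isclose(multiple_correlation(df), r**2, atol=1e-12)

    def test_null_r2_matches_expectation(self):
        """Independent response: E[R^2] = p/(N-1) under the null."""
        rng = np.random.default_rng(8)
        p, n, reps = 4, 60, 300
        r2s = []
        for _ in range(reps):
            df = pd.DataFrame(rng.normal(size=(n, p + 1)),
                              columns=["speed_um_per_h"] + [f"x{i}" for i in range(p)])
            r2s.append(multiple_correlation(df))
        assert abs(np.mean(r2s) - p / (n - 1)) < 0.02

    def test_missing_response_raises(self):
        with pytest.raises(KeyError):
            multiple_correlation(make_table(), response="nope")


class TestJackknife:
    def test_perfect_pair_mean_one_sd_zero(self):
        df = pd.DataFrame({"f": np.arange(10.0), "e": np.arange(10.0) ** 2})
        out = jackknife_correlation(df, ["f"], ["e"])
        assert np.isclose(out.loc["f", "e_mean"], 1.0)
        assert np.isclose(out.loc["f", "e_sd"], 0.0)

    def test_matches_brute_force_delete_one(self):
        df = make_table(n=15, seed=9)
        out = jackknife_correlation(df, ["speed_um_per_h"], ["ProVL_um_per_min"])
        f = df["speed_um_per_h"].to_numpy()
        e = df["ProVL_um_per_min"].to_numpy()
        loo = np.array([
            stats.spearmanr(np.delete(f, i), np.delete(e, i)).statistic
            for i in range(15)
        ])
        assert np.isclose(out.loc["speed_um_per_h", "ProVL_um_per_min_mean"], loo.mean())
        assert np.isclose(out.loc["speed_um_per_h", "ProVL_um_per_min_sd"],
                          loo.std(ddof=1))

    def test_outlier_inflates_jackknife_sd(self):
        rng = np.random.default_rng(10)
        f = rng.normal(size=20)
        e = f + rng.normal(0, 0.2, 20)
        clean = pd.DataFrame({"f": f, "e": e})
        dirty = clean.copy()
        dirty.loc[0, "e"] = 40.0  # gross outlier
        sd_clean = jackknife_correlation(clean, ["f"], ["e"], method="pearson").loc["f", "e_sd"]
        sd_dirty = jackknife_correlation(dirty, ["f"], ["e"], method="pearson").loc["f", "e_sd"]
        assert sd_dirty > sd_clean

    def test_constant_influence_equals_full_sample(self):
        """When all delete-one values coincide, the mean equals the
        full-sample correlation (monotone pair)."""
        df = pd.DataFrame({"f": np.arange(8.0), "e": np.arange(8.0)})
        out = jackknife_correlation(df, ["f"], ["e"])
        assert out.loc["f", "e_mean"] == stats.spearmanr(df.f, df.e).statistic == 1.0


class TestFactorAnalysis:
    def test_identity_covariance_eigenvalues_near_one(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(4000, 6))
        fa = CovarianceFactorAnalysis(n_factors=6, rotation=None).fit(x)
        assert np.allclose(fa.corr_eigenvalues_, 1.0, atol=0.15)
        assert np.all(np.diff(fa.cumulative_variance_) > 0)
        assert fa.cumulative_variance_[-1] <= 100 + 1e-9

    def test_rank_one_structure_single_factor(self):
        rng = np.random.default_rng(12)
        f = rng.normal(size=(500, 1))
        x = f @ np.array([[1.0, 2.0, -1.5]]) + rng.normal(0, 0.05, (500, 3))
        fa = CovarianceFactorAnalysis().fit(x)
        assert fa.n_factors_ == 1
        assert fa.variance_explained_[0] > 95.0

    def test_two_latent_factors_recovered_with_congruence(self):
        """Tucker congruence >= 0.95 against the generating loadings, up to
        sign and permutation."""
        rng = np.random.default_rng(13)
        n = 1000
        load = np.array(
            [[0.9, 0.0], [0.8, 0.0], [0.7, 0.0], [0.0, 0.9], [0.0, 0.8], [0.0, 0.7]]
        )
        f = rng.normal(size=(n, 2))
        x = f @ load.T + rng.normal(0, 0.3, (n, 6))
        fa = CovarianceFactorAnalysis(n_factors=2).fit(x)
        got = fa.loadings_
        cong = np.abs(
            (load.T @ got) /
            np.sqrt(np.outer((load**2).sum(0), (got**2).sum(0)))
        )
        # each generating factor matched by exactly one recovered factor
        assert np.all(cong.max(axis=1) >= 0.95)
        assert set(np.argmax(cong, axis=1)) == {0, 1}

    def test_trace_conservation(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(300, 5)) @ rng.normal(size=(5, 5))
        fa = CovarianceFactorAnalysis(n_factors=5, rotation=None).fit(x)
        assert np.isclose(fa.eigenvalues_.sum(), np.trace(fa.covariance_), atol=1e-8)

    def test_kaiser_retention_counts_correlation_eigenvalues(self):
        rng = np.random.default_rng(15)
        f = rng.normal(size=(800, 2))
        x = np.column_stack([f[:, 0], f[:, 0] + rng.normal(0, 0.4, 800),
                             f[:, 1], f[:, 1] + rng.normal(0, 0.4, 800)])
        fa = CovarianceFactorAnalysis().fit(x)
        assert fa.n_factors_ == int(np.sum(fa.corr_eigenvalues_ >= 1.0))

    def test_loading_table_suppression(self):
        df = make_table(n=200, seed=16)
        fa = factor_analysis(df)
        tab = fa.loading_table(feature_names=fa.feature_names_, threshold=0.4)
        vals = tab.to_numpy()
        shown = vals[~np.isnan(vals)]
        assert np.all(np.abs(shown) >= 0.4)

    def test_requires_more_samples_than_features(self):
        with pytest.raises(ValueError):
            CovarianceFactorAnalysis().fit(np.zeros((4, 6)))
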