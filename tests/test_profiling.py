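"""Profiling: GMM-EM, MDL order selection, two-phase K-means, diagnostics."""

import numpy as np
import pytest
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from morphodyn.profiling import (
    MDLGaussianMixture,
    TwoPhaseKMeans,
    chisq_gof_normal,
    fit_gmm_em,
    mdl_score,
    probability_plot_coords,
    select_k,
    two_phase_kmeans,
)
from morphodyn.simulate import simulate_feature_table


@pytest.fixture(scope="module")
def two_blob_data():
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 1.0, (300, 2))
    b = rng.normal(8.0, 1.0, (300, 2))
    return np.vstack([a, b]), np.repeat([0, 1], 300)


class TestGMMEM:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(3.0, 2.0, (200, 3))
        m = fit_gmm_em(x, 1, random_state=0)
        assert np.allclose(m.means_[0], x.mean(axis=0), atol=1e-8)
        ml_cov = np.cov(x.T, bias=True)
        assert np.allclose(m.covariances_[0], ml_cov, atol=1e-4)
        assert np.isclose(m.weights_[0], 1.0)

    def test_two_separated_components_recovered(self, two_blob_data):
        x, _ = two_blob_data
        m = fit_gmm_em(x, 2, random_state=0)
        means = m.means_[np.argsort(m.means_[:, 0])]
        assert np.linalg.norm(means[0] - 0.0) < 0.1
        assert np.linalg.norm(means[1] - 8.0) < 0.1
        assert np.allclose(m.weights_, 0.5, atol=0.05)

    def test_log_likelihood_monotone_every_iteration(self, two_blob_data):
        x, _ = two_blob_data
        m = fit_gmm_em(x, 3, random_state=2)
        assert np.all(np.diff(m.ll_curve_) >= -1e-7)

    def test_weights_sum_to_one(self, two_blob_data):
        x, _ = two_blob_data
        for k in (1, 2, 4):
            m = fit_gmm_em(x, k, random_state=0)
            assert abs(m.weights_.sum() - 1.0) < 1e-12

    def test_duplicate_points_keep_covariance_pd(self):
        x = np.vstack([np.zeros((50, 2)), np.ones((50, 2)) * 5])
        m = fit_gmm_em(x, 2, random_state=0)
        for c in m.covariances_:
            assert np.min(np.linalg.eigvalsh(c)) > 0

    def test_matches_sklearn_likelihood(self, two_blob_data):
        """Independent oracle: sklearn's EM reaches the same log-likelihood
        per sample (within 1e-3) on well-separated data."""
        x, _ = two_blob_data
        ours = fit_gmm_em(x, 2, random_state=0)
        ref = GaussianMixture(2, n_init=3, random_state=0, reg_covar=1e-6).fit(x)
        assert np.isclose(ours.log_likelihood_ / len(x), ref.score(x), atol=1e-3)


class TestMDL:
    def test_hand_computed_tiny_case(self):
        """K=1, n=1, 4 points: MDL = -log L + 0.5 * 2 * log(4)."""
        x = np.array([[0.0], [1.0], [2.0], [3.0]])
        m = MDLGaussianMixture(1, reg_covar=0.0, random_state=0).fit(x)
        mu, var = 1.5, 1.25  # ML estimates
        loglik = np.sum(stats.norm.logpdf(x.ravel(), mu, np.sqrt(var)))
        expected = -loglik + 0.5 * 2 * np.log(4 * 1)
        assert abs(mdl_score(m, x) - expected) < 1e-10

    def test_penalty_structure_nested_models(self, two_blob_data):
        x, _ = two_blob_data
        lls, pens = [], []
        for k in (1, 2, 3):
            m = fit_gmm_em(x, k, random_state=0)
            lls.append(m.log_likelihood_)
            pens.append(0.5 * m.n_parameters_ * np.log(x.size))
        assert lls[0] <= lls[1] + 1e-6 and lls[1] <= lls[2] + 1e-6
        assert pens[0] < pens[1] < pens[2]

    def test_penalty_grows_with_replication(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(50, 2))
        m = fit_gmm_em(x, 1, random_state=0)
        pen_small = mdl_score(m, x) + m.score_samples(x).sum()
        x10 = np.tile(x, (10, 1))
        m10 = fit_gmm_em(x10, 1, random_state=0)
        pen_big = mdl_score(m10, x10) + m10.score_samples(x10).sum()
        assert np.isclose(pen_big - pen_small,
                          0.5 * m.n_parameters_ * np.log(10), atol=1e-9)


class TestSelectK:
    def test_four_reference_classes_recovered(self):
        """MDL minimum lands at K=4 on the four-class feature mixture."""
        df = simulate_feature_table(n_samples=2000, seed=0)
        x = df.drop(columns="true_class").to_numpy()
        x = (x - x.mean(0)) / x.std(0)
        res = select_k(x, 2, 8, random_state=0)
        assert res.k_best == 4

    def test_single_gaussian_prefers_small_k(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(500, 3))
        res = select_k(x, 1, 4, random_state=0)
        assert res.k_best <= 2
        assert res.mdl_by_k[1] < res.mdl_by_k[4]

    def test_degenerate_range(self, two_blob_data):
        x, _ = two_blob_data
        res = select_k(x, 2, 2, random_state=0)
        assert res.k_best == 2

    def test_k_max_clipped_with_warning(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(20, 2))
        with pytest.warns(UserWarning, match="clipped"):
            select_k(x, 2, 50, random_state=0)


class TestTwoPhaseKMeans:
    def test_well_separated_blobs_recovered(self, two_blob_data):
        x, truth = two_blob_data
        est = TwoPhaseKMeans(2, random_state=0).fit(x)
        # agreement up to label permutation
        agree = max(np.mean(est.labels_ == truth), np.mean(est.labels_ != truth))
        assert agree == 1.0

    def test_objective_close_to_plain_kmeans(self, two_blob_data):
        x, _ = two_blob_data
        est = TwoPhaseKMeans(2, random_state=0).fit(x)
        ref = KMeans(2, n_init=10, random_state=0).fit(x)
        assert est.inertia_ <= ref.inertia_ * 1.01

    def test_descent_from_phase1_centroids(self, two_blob_data):
        x, _ = two_blob_data
        est = TwoPhaseKMeans(2, random_state=1).fit(x)
        d = np.linalg.norm(x[:, None, :] - est.phase1_centers_[None], axis=2)
        phase1_obj = np.sum(np.min(d, axis=1) ** 2)
        assert est.inertia_ <= phase1_obj + 1e-9

    def test_k1_gives_grand_mean(self, two_blob_data):
        x, _ = two_blob_data
        est = TwoPhaseKMeans(1, random_state=0).fit(x)
        assert np.allclose(est.cluster_centers_[0], x.mean(axis=0), atol=1e-9)

    def test_k_exceeding_sample_rejected(self):
        x = np.random.default_rng(0).normal(size=(50, 2))
        with pytest.raises(ValueError, match="phase-1"):
            TwoPhaseKMeans(10, sample_frac=0.1, random_state=0).fit(x)

    def test_functional_wrapper(self, two_blob_data):
        x, _ = two_blob_data
        labels, centers, inertia = two_phase_kmeans(x, 2, random_state=0)
        assert labels.shape == (600,) and centers.shape == (2, 2) and inertia > 0


class TestProbabilityPlot:
    def test_midpoints_formula_n4(self):
        pp = probability_plot_coords([3.0, 1.0, 2.0, 4.0])
        assert np.allclose(pp.midpoints, [0.125, 0.375, 0.625, 0.875])
        assert np.array_equal(pp.sorted_values, [1.0, 2.0, 3.0, 4.0])

    def test_exact_normal_quantiles_lie_on_reference_line(self):
        n = 101
        x = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n, loc=5.0, scale=2.0)
        pp = probability_plot_coords(x)
        fitted = pp.slope * pp.quantiles + pp.intercept
        assert np.max(np.abs(fitted - pp.sorted_values)) < 0.15  # tails only

    def test_heavy_tails_depart_from_line(self):
        rng = np.random.default_rng(7)
        x = rng.standard_cauchy(500)
        pp = probability_plot_coords(x)
        fitted = pp.slope * pp.quantiles + pp.intercept
        resid = pp.sorted_values - fitted
        # both extreme tails overshoot the normal reference line
        assert resid[:10].mean() < 0 and resid[-10:].mean() > 0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            probability_plot_coords([1.0, 2.0, 3.0])


class TestChisqGofNormal:
    def test_perfect_normal_quantile_sample(self):
        """Counts exactly equal to expected: chi2 = 0, p = 1."""
        n, bins = 200, 10
        x = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        chi2, df, p = chisq_gof_normal(x, n_bins=bins)
        assert chi2 <= bins  # quantile sample is near-perfectly uniform in bins
        assert df == bins - 3

    def test_type_one_error_rate_near_nominal(self):
        """Normal data: rejection rate at alpha=0.05 close to 5%."""
        rng = np.random.default_rng(8)
        rejects = sum(
            chisq_gof_normal(rng.normal(size=300), 10)[2] < 0.05 for _ in range(400)
        )
        assert 0.02 <= rejects / 400 <= 0.09

    def test_uniform_sample_rejected_with_power(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(-1, 1, 1000)
        _, _, p = chisq_gof_normal(x, 10)
        assert p < 0.01

    def test_sample_size_guard(self):
        with pytest.raises(ValueError):
            chisq_gof_normal(np.random.default_rng(0).normal(size=30), 10)
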