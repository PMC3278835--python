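"""Subpopulation discovery: Gaussian mixtures with MDL order selection,
two-phase K-means, and normality diagnostics.

Cell classes are found by fitting full-covariance Gaussian mixture models by
expectation-maximisation for every candidate order K and choosing the K that
minimises the minimum description length

    MDL(K) = -log L(Theta) + (1/2) * L_p * log(N * n),

where ``L_p = K (1 + n + n(n+1)/2) - 1`` counts the free parameters of a
K-component mixture over n features and N is the sample count; the penalty
includes the feature count to resist over-fitting.  Within each cell class,
edge-print subclasses are then found by two-phase K-means: a clustering pass
on a random 10% subsample supplies the initial centroids for a full-data
pass, removing the usual sensitivity to K-means initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin, DensityMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "MDLGaussianMixture",
    "TwoPhaseKMeans",
    "ModelSelectionResult",
    "fit_gmm_em",
    "mdl_score",
    "select_k",
    "two_phase_kmeans",
    "probability_plot_coords",
    "chisq_gof_normal",
    "ProbabilityPlot",
]


def _log_gaussian(x, mean, chol):
    """Log density of N(mean, L L^T) at rows of x, given Cholesky factor L."""
    n = x.shape[1]
    diff = x - mean
    sol = np.linalg.solve(chol, diff.T).T
    maha = np.sum(sol**2, axis=1)
    logdet = 2 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (n * np.log(2 * np.pi) + logdet + maha)


class MDLGaussianMixture(DensityMixin, BaseEstimator):
    """Full-covariance Gaussian mixture fitted by EM, scored by MDL.

    Parameters
    ----------
    n_components : int
        Number of mixture components K (>= 1).
    max_restarts : int
        EM is restarted with fresh K-means initial conditions until a run
        converges, at most this many times; among executed converged runs the
        best log-likelihood wins.
    tol : float
        Convergence: absolute change in mean per-sample log-likelihood.
    max_iter : int
        EM iteration cap per restart.
    reg_covar : float or "auto"
        Ridge added to covariance diagonals to keep them positive definite;
        "auto" uses 1e-6 times the mean feature variance.
    random_state : int or Generator
        Seeds the K-means initialisations.

    Attributes
    ----------
    weights_, means_, covariances_ : mixture parameters (weights sum to 1).
    log_likelihood_ : total log-likelihood of the training data.
    ll_curve_ : per-iteration log-likelihood of the winning run
        (non-decreasing by the EM monotonicity property).
    converged_ : whether any restart converged.
    mdl_ : MDL score on the training data.
    """

    def __init__(self, n_components=1, max_restarts=5, tol=1e-6, max_iter=500,
                 reg_covar="auto", random_state=None):
        self.n_components = n_components
        self.max_restarts = max_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.reg_covar = reg_covar
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _e_step(self, x, weights, means, chols):
        logp = np.stack(
            [np.log(w) + _log_gaussian(x, m, c) for w, m, c in zip(weights, means, chols)],
            axis=1,
        )
        norm = logsumexp(logp, axis=1)
        return np.exp(logp - norm[:, None]), float(norm.sum())

    def _m_step(self, x, resp, reg):
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / x.shape[0]
        means = (resp.T @ x) / nk[:, None]
        covs = []
        for k in range(resp.shape[1]):
            diff = x - means[k]
            cov = (resp[:, k][:, None] * diff).T @ diff / nk[k]
            cov.flat[:: cov.shape[0] + 1] += reg
            covs.append(cov)
        return weights, means, np.stack(covs)

    def _run_em(self, x, rng, reg):
        k = self.n_components
        km = KMeans(n_clusters=k, n_init=1,
                    random_state=int(rng.integers(2**31 - 1))).fit(x)
        labels = km.labels_
        weights = np.bincount(labels, minlength=k).astype(float)
        weights = np.maximum(weights, 1.0)
        weights /= weights.sum()
        means = km.cluster_centers_.copy()
        covs = []
        global_cov = np.cov(x.T).reshape(x.shape[1], x.shape[1])
        for j in range(k):
            xk = x[labels == j]
            cov = np.cov(xk.T).reshape(x.shape[1], x.shape[1]) if len(xk) > 1 else global_cov.copy()
            cov.flat[:: cov.shape[0] + 1] += reg
            covs.append(cov)
        covs = np.stack(covs)

        ll_curve = []
        converged = False
        prev = -np.inf
        for _ in range(self.max_iter):
            chols = [np.linalg.cholesky(c) for c in covs]
            resp, ll = self._e_step(x, weights, means, chols)
            ll_curve.append(ll)
            if np.abs(ll - prev) / x.shape[0] < self.tol:
                converged = True
                break
            prev = ll
            weights, means, covs = self._m_step(x, resp, reg)
        return dict(weights=weights, means=means, covs=covs, ll=ll_curve[-1],
                    ll_curve=np.array(ll_curve), converged=converged)

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None):
        x = check_array(X, dtype=float)
        if self.n_components < 1 or x.shape[0] < self.n_components:
            raise ValueError("need n_samples >= n_components >= 1")
        rng = np.random.default_rng(self.random_state)
        reg = (
            1e-6 * float(np.mean(np.var(x, axis=0)))
            if self.reg_covar == "auto"
            else float(self.reg_covar)
        )
        reg = max(reg, 1e-12)
        best = None
        for _ in range(self.max_restarts):
            run = self._run_em(x, rng, reg)
            if run["converged"] and (best is None or run["ll"] > best["ll"]):
                if best is None or not best["converged"] or run["ll"] > best["ll"]:
                    best = run
            elif best is None:
                best = run
            if best is not None and best["converged"]:
                break
        self.weights_ = best["weights"]
        self.means_ = best["means"]
        self.covariances_ = best["covs"]
        self.log_likelihood_ = best["ll"]
        self.ll_curve_ = best["ll_curve"]
        self.converged_ = bool(best["converged"])
        self.reg_covar_ = reg
        self.n_features_in_ = x.shape[1]
        self.mdl_ = self.mdl(x)
        return self

    def _logpdf_components(self, x):
        chols = [np.linalg.cholesky(c) for c in self.covariances_]
        return np.stack(
            [np.log(w) + _log_gaussian(x, m, c)
             for w, m, c in zip(self.weights_, self.means_, chols)],
            axis=1,
        )

    def score_samples(self, X):
        check_is_fitted(self, "weights_")
        x = check_array(X, dtype=float)
        return logsumexp(self._logpdf_components(x), axis=1)

    def score(self, X, y=None):
        return float(np.mean(self.score_samples(X)))

    def predict_proba(self, X):
        logp = self._logpdf_components(check_array(X, dtype=float))
        return np.exp(logp - logsumexp(logp, axis=1)[:, None])

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)

    @property
    def n_parameters_(self) -> int:
        n = self.n_features_in_
        return self.n_components * (1 + n + n * (n + 1) // 2) - 1

    def mdl(self, X) -> float:
        """MDL = -log L + 0.5 * L_p * log(N * n) on the given data."""
        x = check_array(X, dtype=float)
        ll = float(self.score_samples(x).sum())
        n_samples, n_feat = x.shape
        return -ll + 0.5 * self.n_parameters_ * np.log(n_samples * n_feat)


def fit_gmm_em(X, n_components, max_restarts=5, tol=1e-6, max_iter=500,
               random_state=None) -> MDLGaussianMixture:
    """Functional wrapper over :class:`MDLGaussianMixture`."""
    return MDLGaussianMixture(
        n_components=n_components, max_restarts=max_restarts, tol=tol,
        max_iter=max_iter, random_state=random_state,
    ).fit(X)


def mdl_score(model: MDLGaussianMixture, X) -> float:
    """MDL score of a fitted mixture on data (lower is better)."""
    return model.mdl(X)


@dataclass
class ModelSelectionResult:
    """Outcome of MDL model-order selection."""

    k_best: int
    mdl_by_k: dict[int, float]
    unconverged: list[int]
    best_model: MDLGaussianMixture

    @property
    def restarts_used(self) -> dict[int, int]:  # pragma: no cover - informational
        return getattr(self, "_restarts", {})


def select_k(X, k_min: int = 2, k_max: int = 100, random_state=None,
             **gmm_kwargs) -> ModelSelectionResult:
    """Fit mixtures for K = k_min..k_max and pick the MDL minimiser.

    ``k_max`` is clipped to N - 1 with a warning when infeasible.  Candidates
    whose restarts all fail to converge are excluded from the minimisation.
    """
    x = check_array(X, dtype=float)
    n = x.shape[0]
    if k_max >= n:
        import warnings

        warnings.warn(f"k_max clipped from {k_max} to {n - 1}", stacklevel=2)
        k_max = n - 1
    if k_min < 1 or k_min > k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    rng = np.random.default_rng(random_state)
    mdl_by_k: dict[int, float] = {}
    unconverged: list[int] = []
    models: dict[int, MDLGaussianMixture] = {}
    for k in range(k_min, k_max + 1):
        model = MDLGaussianMixture(
            n_components=k, random_state=int(rng.integers(2**31 - 1)), **gmm_kwargs
        ).fit(x)
        if not model.converged_:
            unconverged.append(k)
            continue
        mdl_by_k[k] = model.mdl_
        models[k] = model
    if not mdl_by_k:
        raise RuntimeError("no candidate order converged")
    k_best = min(mdl_by_k, key=mdl_by_k.get)
    return ModelSelectionResult(k_best=k_best, mdl_by_k=mdl_by_k,
                                unconverged=unconverged, best_model=models[k_best])


class TwoPhaseKMeans(ClusterMixin, BaseEstimator):
    """K-means seeded by centroids from a preliminary pass on a 10% subsample.

    Phase 1 clusters a uniform random ``sample_frac`` fraction of the rows;
    its centroids seed phase 2 on all rows, which therefore starts from a
    configuration already adapted to the data and can only improve the
    within-cluster sum of squares.

    Attributes: ``cluster_centers_``, ``labels_``, ``inertia_`` (final
    within-cluster sum of squares), ``phase1_centers_``.
    """

    def __init__(self, n_clusters=2, sample_frac=0.10, n_iter=1000, random_state=None):
        self.n_clusters = n_clusters
        self.sample_frac = sample_frac
        self.n_iter = n_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        x = check_array(X, dtype=float)
        n = x.shape[0]
        m = int(np.floor(self.sample_frac * n))
        if self.n_clusters > m:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds the phase-1 sample size {m}"
            )
        rng = np.random.default_rng(self.random_state)
        idx = rng.choice(n, size=m, replace=False)
        km1 = KMeans(n_clusters=self.n_clusters, n_init=1, max_iter=self.n_iter,
                     random_state=int(rng.integers(2**31 - 1))).fit(x[idx])
        km2 = KMeans(n_clusters=self.n_clusters, init=km1.cluster_centers_, n_init=1,
                     max_iter=self.n_iter).fit(x)
        self.phase1_centers_ = km1.cluster_centers_
        self.cluster_centers_ = km2.cluster_centers_
        self.labels_ = km2.labels_
        self.inertia_ = float(km2.inertia_)
        self.n_features_in_ = x.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        x = check_array(X, dtype=float)
        d = np.linalg.norm(x[:, None, :] - self.cluster_centers_[None], axis=2)
        return np.argmin(d, axis=1)


def two_phase_kmeans(X, n_clusters, sample_frac=0.10, n_iter=1000, random_state=None):
    """Functional wrapper: returns (labels, centers, inertia)."""
    est = TwoPhaseKMeans(n_clusters=n_clusters, sample_frac=sample_frac,
                         n_iter=n_iter, random_state=random_state).fit(X)
    return est.labels_, est.cluster_centers_, est.inertia_


# ---------------------------------------------------------------------------
# Normality diagnostics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbabilityPlot:
    """Normal probability plot coordinates.

    ``midpoints`` are the empirical-CDF jump midpoints (j - 0.5)/N of the
    sorted sample; ``quantiles`` their probit transform (the plot ordinate on
    a probability scale, on which a normal sample is linear).  The reference
    line ``value = slope * quantile + intercept`` joins the first and third
    quartile points.
    """

    sorted_values: np.ndarray
    midpoints: np.ndarray
    quantiles: np.ndarray
    slope: float
    intercept: float


def probability_plot_coords(x) -> ProbabilityPlot:
    """Coordinates for a normal probability plot with quartile reference line."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    midpoints = (np.arange(1, n + 1) - 0.5) / n
    quantiles = stats.norm.ppf(midpoints)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    z1, z3 = stats.norm.ppf([0.25, 0.75])
    slope = (q3 - q1) / (z3 - z1)
    intercept = q1 - slope * z1
    return ProbabilityPlot(sorted_values=x, midpoints=midpoints, quantiles=quantiles,
                           slope=float(slope), intercept=float(intercept))


def chisq_gof_normal(x, n_bins: int = 10) -> tuple[float, int, float]:
    """Chi-square goodness-of-fit test against a fitted normal.

    Bins are equal-probability under N(mean, sd) with moment estimates, so
    each expected count is N/n_bins; the statistic is referred to a
    chi-square with ``n_bins - 3`` degrees of freedom (two parameters
    estimated).  Requires N >= 5 * n_bins for the usual expected-count rule.

    Returns (chi2, df, p).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 5 * n_bins:
        raise ValueError("need N >= 5 * n_bins observations")
    mean, sd = x.mean(), x.std(ddof=1)
    if sd <= 0:
        raise ValueError("sample is constant")
    edges = stats.norm.ppf(np.linspace(0, 1, n_bins + 1), loc=mean, scale=sd)
    observed, _ = np.histogram(x, bins=edges)
    expected = n / n_bins
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    df = n_bins - 3
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p
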