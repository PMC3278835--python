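"""Association between whole-cell motility and edge dynamics.

Per cell class, the eight motility features are compared with the two
time-averaged edge features — mean protrusion velocity (ProVL) and mean
retraction velocity (RetVL) — via:

* Spearman rank correlation with p-values from the t transform
  ``t = rho * sqrt((N - 2) / (1 - rho^2))`` on N - 2 degrees of freedom,
  flagged at alpha = 0.05 (Benjamini-Hochberg-adjusted flags are also
  emitted);
* multiple correlation: R^2 of an OLS regression of speed on all other
  features;
* leave-one-out jackknife of each (motility, edge) correlation, reported as
  mean +/- sd of the N delete-one estimates;
* factor analysis of the full feature set (8 motility + all edge-print
  features): principal-axis extraction from the covariance matrix, Kaiser
  retention (eigenvalues of the correlation-scaled matrix >= 1), varimax
  rotation, with per-factor and cumulative variance percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .edge import EdgePrint

__all__ = [
    "CorrelationReport",
    "CovarianceFactorAnalysis",
    "time_average_edge",
    "spearman_with_p",
    "multiple_correlation",
    "jackknife_correlation",
    "factor_analysis",
]


def time_average_edge(print_: EdgePrint) -> tuple[float, float]:
    """(ProVL, RetVL): time-averaged protrusion and retraction velocity, um/min."""
    return float(np.mean(print_.protrusion)), float(np.mean(print_.retraction))


def _spearman_matrix(values: np.ndarray) -> np.ndarray:
    ranks = np.apply_along_axis(stats.rankdata, 0, values)  # average ranks for ties
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    return rho


def _t_transform_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from t = rho * sqrt((N-2)/(1-rho^2)), N-2 d.f."""
    rho_c = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho_c * np.sqrt((n - 2) / (1 - rho_c**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho_c), 1.0), 0.0, p)
    return p


@dataclass
class CorrelationReport:
    """Pairwise Spearman matrix with significance flags."""

    rho: pd.DataFrame
    p_values: pd.DataFrame
    significant: pd.DataFrame  # raw p < alpha (the headline convention)
    significant_bh: pd.DataFrame  # Benjamini-Hochberg adjusted flags
    alpha: float
    n: int


def spearman_with_p(table: pd.DataFrame, alpha: float = 0.05) -> CorrelationReport:
    """Spearman correlation matrix over the numeric columns of ``table``.

    Requires N >= 4 rows.  The diagonal has rho = 1, p = 0.
    """
    cols = [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    values = table[cols].to_numpy(dtype=float)
    n = values.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples")
    rho = _spearman_matrix(values)
    p = _t_transform_p(rho, n)
    np.fill_diagonal(p, 0.0)

    from statsmodels.stats.multitest import multipletests

    iu = np.triu_indices_from(p, k=1)
    flat = p[iu]
    rej = multipletests(flat, alpha=alpha, method="fdr_bh")[0]
    bh = np.zeros_like(p, dtype=bool)
    bh[iu] = rej
    bh = bh | bh.T

    as_df = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return CorrelationReport(
        rho=as_df(rho), p_values=as_df(p), significant=as_df(p < alpha),
        significant_bh=as_df(bh), alpha=alpha, n=n,
    )


def multiple_correlation(table: pd.DataFrame, response: str = "speed_um_per_h") -> float:
    """R^2 of an OLS fit of ``response`` on all other numeric features."""
    import statsmodels.api as sm

    cols = [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    if response not in cols:
        raise KeyError(f"response column {response!r} not in table")
    y = table[response].to_numpy(dtype=float)
    x = table[[c for c in cols if c != response]].to_numpy(dtype=float)
    if y.size <= x.shape[1] + 1:
        raise ValueError("need N > number of predictors")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.rsquared)


def _corr(x, y, method):
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.pearsonr(x, y).statistic)


def jackknife_correlation(
    table: pd.DataFrame,
    feature_cols: list[str],
    edge_cols: list[str],
    method: str = "spearman",
) -> pd.DataFrame:
    """Leave-one-out jackknife of each (feature, edge feature) correlation.

    For every pair the correlation is recomputed N times with one cell left
    out; the mean and standard deviation (ddof=1) of the N delete-one values
    are reported.  Rows: feature_cols; column pairs ``<edge>_mean`` and
    ``<edge>_sd``.
    """
    n = len(table)
    if n < 3:
        raise ValueError("need at least 3 samples for the jackknife")
    out = {}
    mask = ~np.eye(n, dtype=bool)
    for ec in edge_cols:
        e = table[ec].to_numpy(dtype=float)
        means, sds = [], []
        for fc in feature_cols:
            f = table[fc].to_numpy(dtype=float)
            loo = np.array([_corr(f[mask[i]], e[mask[i]], method) for i in range(n)])
            means.append(loo.mean())
            sds.append(loo.std(ddof=1))
        out[f"{ec}_mean"] = means
        out[f"{ec}_sd"] = sds
    return pd.DataFrame(out, index=feature_cols)


def _varimax(loadings: np.ndarray) -> np.ndarray:
    from statsmodels.multivariate.factor_rotation import rotate_factors

    if loadings.shape[1] < 2:
        return loadings
    rotated, _ = rotate_factors(loadings, "varimax")
    return rotated


class CovarianceFactorAnalysis(TransformerMixin, BaseEstimator):
    """Principal-axis factor analysis of the covariance matrix.

    Loadings are eigenvector columns scaled by the square roots of their
    eigenvalues.  The number of retained factors follows the Kaiser
    criterion applied to the eigenvalues of the correlation-scaled matrix
    (>= 1), unless ``n_factors`` fixes it; retained loadings are varimax
    rotated by default.  Loadings from the correlation matrix are kept
    alongside (``loadings_corr_``) since suppression thresholds such as 0.4
    refer to the standardised scale.

    Attributes
    ----------
    eigenvalues_ : covariance-matrix eigenvalues, descending.
    corr_eigenvalues_ : correlation-matrix eigenvalues, descending.
    n_factors_ : retained factor count.
    loadings_ : (n_features, n_factors) rotated covariance-scale loadings.
    loadings_corr_ : rotated correlation-scale loadings.
    variance_explained_ : percent of total variance per retained factor,
        decreasing.
    cumulative_variance_ : running sum of the above.
    """

    def __init__(self, n_factors=None, rotation="varimax", ridge=1e-10):
        self.n_factors = n_factors
        self.rotation = rotation
        self.ridge = ridge

    def fit(self, X, y=None):
        x = check_array(X, dtype=float)
        n_samples, n_feat = x.shape
        if n_samples <= n_feat:
            raise ValueError("need more samples than features")
        cov = np.cov(x, rowvar=False)
        cov.flat[:: n_feat + 1] += self.ridge * np.trace(cov) / n_feat
        sd = np.sqrt(np.diag(cov))
        corr = cov / np.outer(sd, sd)

        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
        corr_evals = np.sort(np.linalg.eigvalsh(corr))[::-1]

        m = (
            int(np.sum(corr_evals >= 1.0)) if self.n_factors is None
            else int(self.n_factors)
        )
        m = max(1, min(m, n_feat))
        load = evecs[:, :m] * np.sqrt(evals[:m])
        load_corr = load / sd[:, None]
        if self.rotation == "varimax":
            load = _varimax(load)
            load_corr = _varimax(load_corr)
        elif self.rotation not in (None, "none"):
            raise ValueError(f"unknown rotation {self.rotation!r}")

        total_var = float(np.trace(cov))
        var_pct = 100.0 * np.sum(load**2, axis=0) / total_var
        order = np.argsort(var_pct)[::-1]
        load, load_corr, var_pct = load[:, order], load_corr[:, order], var_pct[order]

        self.mean_ = x.mean(axis=0)
        self.covariance_ = cov
        self.eigenvalues_ = evals
        self.corr_eigenvalues_ = corr_evals
        self.n_factors_ = m
        self.loadings_ = load
        self.loadings_corr_ = load_corr
        self.variance_explained_ = var_pct
        self.cumulative_variance_ = np.cumsum(var_pct)
        self.n_features_in_ = n_feat
        return self

    def transform(self, X):
        """Factor scores by least squares on the centred data."""
        check_is_fitted(self, "loadings_")
        x = check_array(X, dtype=float) - self.mean_
        return x @ np.linalg.pinv(self.loadings_.T)

    def loading_table(
        self, feature_names=None, threshold: float = 0.4, standardized: bool = True
    ) -> pd.DataFrame:
        """Report-style loading matrix with |loading| < threshold suppressed.

        Suppression applies to the standardised (correlation-scale) loadings
        by default; set ``standardized=False`` for the raw covariance scale.
        """
        check_is_fitted(self, "loadings_")
        load = self.loadings_corr_ if standardized else self.loadings_
        out = pd.DataFrame(
            np.where(np.abs(load) >= threshold, load, np.nan),
            index=feature_names if feature_names is not None
            else [f"feature_{i}" for i in range(load.shape[0])],
            columns=[f"factor_{j + 1}" for j in range(load.shape[1])],
        )
        return out


def factor_analysis(table: pd.DataFrame, n_factors=None, rotation="varimax"):
    """Fit :class:`CovarianceFactorAnalysis` on the numeric columns of a table."""
    cols = [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    est = CovarianceFactorAnalysis(n_factors=n_factors, rotation=rotation)
    est.fit(table[cols].to_numpy(dtype=float))
    est.feature_names_ = cols
    return est
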