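"""Whole-cell motility features from the persistent random walk (PRW) model.

The geometric centroid track of each cell is summarised by eight features:
speed S (um/h) and persistence P (h) from a weighted fit of the PRW
mean-squared-displacement model

    <d^2(t)> = 2 S^2 P [t - P (1 - exp(-t/P))],

plus chemotactic index CI = TD/TPL, total path length TPL, total displacement
TD, random motility coefficient RMC = S^2 P / 2 (the 2-D long-time diffusion
coefficient), mean path length MPL = TPL/(T-1), and persistence length
PrL = S * P.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import prw_msd_theory

__all__ = [
    "MSDCurve",
    "PRWFit",
    "MotilityFeatures",
    "compute_msd",
    "fit_prw",
    "motility_features",
    "persistence_length",
]


@dataclass(frozen=True)
class MSDCurve:
    """Mean squared displacement versus lag time.

    ``lags`` are in hours, ``msd`` in um^2, and ``n_pairs`` counts the
    overlapping interval pairs averaged at each lag.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("MSD cannot be negative")


@dataclass(frozen=True)
class PRWFit:
    """Result of fitting the PRW MSD model."""

    speed: float  # S, um/h
    persistence: float  # P, h
    cost: float
    converged: bool
    flag: str = ""  # "", "ballistic", "fallback"


@dataclass(frozen=True)
class MotilityFeatures:
    """The eight whole-cell dynamics features of one track (um / h units)."""

    speed: float
    persistence: float
    chemotactic_index: float
    total_path_length: float
    total_displacement: float
    random_motility_coefficient: float
    mean_path_length: float
    persistence_length: float
    fit_flag: str = ""

    def as_dict(self) -> dict[str, float]:
        return {
            "speed_um_per_h": self.speed,
            "persistence_h": self.persistence,
            "chemotactic_index": self.chemotactic_index,
            "total_path_length_um": self.total_path_length,
            "total_displacement_um": self.total_displacement,
            "random_motility_coefficient_um2_per_h": self.random_motility_coefficient,
            "mean_path_length_um": self.mean_path_length,
            "persistence_length_um": self.persistence_length,
        }


def persistence_length(speed: float, persistence: float) -> float:
    """PrL = S * P: characteristic distance before direction decorrelates (um)."""
    return speed * persistence


def compute_msd(
    positions: np.ndarray,
    pixel_size: float = 1.0,
    frame_interval: float = 10.0,
) -> MSDCurve:
    """MSD over all lags 1..T-1 with overlapping-interval averaging.

    Parameters
    ----------
    positions : (T, 2) ndarray
        Centroid positions per frame.  Interpreted as pixels and converted to
        um with ``pixel_size``; pass ``pixel_size=1`` for positions already
        in um.
    frame_interval : float
        Minutes between frames.
    """
    pos = np.asarray(positions, dtype=float) * pixel_size
    t = pos.shape[0]
    if pos.ndim != 2 or t < 3:
        raise ValueError("need a (T>=3, 2) position array")
    dt_h = frame_interval / 60.0
    lags = np.arange(1, t) * dt_h
    msd = np.empty(t - 1)
    n_pairs = np.empty(t - 1, dtype=int)
    for k in range(1, t):
        d = pos[k:] - pos[:-k]
        msd[k - 1] = np.mean(np.sum(d * d, axis=1))
        n_pairs[k - 1] = t - k
    return MSDCurve(lags=lags, msd=msd, n_pairs=n_pairs)


def _msd_shape(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    """g(t; P) = 2 P [t - P (1 - exp(-t/P))], so that MSD = S^2 g.

    Evaluated stably: for t/P << 1 the bracket suffers catastrophic
    cancellation, so a Taylor series is used there.
    """
    h = t / p
    small = h < 1e-4
    f = np.where(small, h * h / 2 - h**3 / 6 + h**4 / 24, h - 1 + np.exp(-np.minimum(h, 700)))
    return 2 * p * p * f


def fit_prw(msd_curve: MSDCurve, n_grid: int = 64) -> PRWFit:
    """Weighted nonlinear least-squares fit of the PRW MSD model.

    The sampling variance of an MSD estimate scales as ``msd^2 / n_pairs``,
    so residuals are relative (per-lag msd scale) with ``sqrt(n_pairs)``
    weight; absolute residuals would let the noisy long lags swamp the
    informative short ones and push single-track fits onto the degenerate
    diffusive ridge (S -> inf, P -> 0 at constant S^2 P).

    Because the model is linear in S^2 at fixed P, S is profiled out in
    closed form and the remaining 1-D problem in P is solved by a dense
    logarithmic grid (multi-start over sub-frame to super-window time
    scales) refined by bounded Brent minimisation; both parameters are
    positive by construction.

    Degenerate fits are flagged rather than silently returned: ``ballistic``
    when the fitted P exceeds 10x the observation window (P is then not
    identified, S remains meaningful), ``fallback`` if the profiled fit is
    degenerate (S from the first lag, P set to the lag spacing).
    """
    lags, msd, npairs = msd_curve.lags, msd_curve.msd, msd_curve.n_pairs
    if lags.size < 3:
        raise ValueError("need at least 3 positive-lag MSD points")
    if np.all(msd < 1e-24):  # stationary track
        return PRWFit(speed=0.0, persistence=lags[0], cost=0.0, converged=True)
    w2 = (npairs / npairs.max()) / np.maximum(msd, 1e-12 * msd.max()) ** 2

    def profiled(p):
        """WLS cost at P with the optimal S^2 substituted."""
        g = _msd_shape(lags, p)
        denom = np.sum(w2 * g * g)
        s2 = max(np.sum(w2 * g * msd) / denom, 0.0) if denom > 0 else 0.0
        r = s2 * g - msd
        return float(np.sum(w2 * r * r)), s2

    p_lo, p_hi = lags[0] / 50.0, lags[-1] * 100.0
    grid = np.geomspace(p_lo, p_hi, n_grid)
    costs = np.array([profiled(p)[0] for p in grid])
    i = int(np.argmin(costs))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    from scipy.optimize import minimize_scalar

    sol = minimize_scalar(lambda p: profiled(p)[0], bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-10 * grid[i]})
    p_best = float(sol.x) if sol.fun <= costs[i] else float(grid[i])
    cost, s2 = profiled(p_best)
    if s2 <= 0:
        s0 = np.sqrt(msd[0]) / lags[0]
        return PRWFit(speed=float(s0), persistence=float(lags[0]), cost=np.inf,
                      converged=False, flag="fallback")
    flag = "ballistic" if p_best > 10 * lags[-1] else ""
    return PRWFit(speed=float(np.sqrt(s2)), persistence=p_best, cost=cost,
                  converged=True, flag=flag)


def motility_features(
    positions: np.ndarray,
    pixel_size: float = 1.0,
    frame_interval: float = 10.0,
) -> MotilityFeatures:
    """Compute the eight motility features of one complete track.

    Path-based features come directly from the centroid polyline; S and P
    come from :func:`fit_prw` on the track's MSD curve.  ``CI = TD/TPL`` is
    defined as 0 for a stationary track.
    """
    pos = np.asarray(positions, dtype=float) * pixel_size
    t = pos.shape[0]
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    tpl = float(steps.sum())
    td = float(np.linalg.norm(pos[-1] - pos[0]))
    ci = td / tpl if tpl > 0 else 0.0
    fit = fit_prw(compute_msd(pos, 1.0, frame_interval))
    s, p = fit.speed, fit.persistence
    return MotilityFeatures(
        speed=s,
        persistence=p,
        chemotactic_index=ci,
        total_path_length=tpl,
        total_displacement=td,
        random_motility_coefficient=s**2 * p / 2.0,
        mean_path_length=tpl / (t - 1),
        persistence_length=persistence_length(s, p),
        fit_flag=fit.flag,
    )
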