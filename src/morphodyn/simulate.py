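"""Synthetic time-lapse movies, tracks and feature tables with ground truth.

Every downstream stage (segmentation, tracking, motility, edge dynamics,
profiling) can be tested against known truth emitted by this module:

* :func:`simulate_prw_track` draws centroid trajectories from an exactly
  discretised persistent random walk (integrated Ornstein-Uhlenbeck velocity
  process), whose ensemble mean-squared displacement follows the closed form
  ``<d^2(t)> = 2 S^2 P [t - P (1 - exp(-t/P))]``.
* :func:`simulate_cell_movie` renders bright star-shaped cells on a dark
  background (12-bit scale) moving on PRW tracks while their boundary
  ``r(theta, t) = R + sum_j a_j sin(f_j theta + phi_j + omega_j t)`` deforms,
  and emits ground-truth label masks, tracks, per-frame marker radii and the
  true edge prints on the same equiangular grid the edge-dynamics module uses.
* :func:`simulate_feature_table` draws labelled samples from a Gaussian
  mixture; its default means are the published mean motility profiles of four
  macrophage (IC-21) subpopulations, so order-selection tests run under
  realistic class geometry.

All generators are bit-reproducible given (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .edge import EdgePrint, edge_print_from_radii, polar_resample

__all__ = [
    "MOTILITY_FEATURE_NAMES",
    "REFERENCE_CLASS_MEANS",
    "SimulationConfig",
    "SimulatedMovie",
    "simulate_prw_track",
    "simulate_prw_tracks",
    "prw_msd_theory",
    "simulate_cell_movie",
    "simulate_feature_table",
    "write_movie",
]

#: Canonical order and units of the eight whole-cell motility features.
MOTILITY_FEATURE_NAMES = (
    "speed_um_per_h",
    "persistence_h",
    "chemotactic_index",
    "total_path_length_um",
    "total_displacement_um",
    "random_motility_coefficient_um2_per_h",
    "mean_path_length_um",
    "persistence_length_um",
)

#: Mean motility-feature profiles of four subpopulations of cultured IC-21
#: macrophages (slow/erratic, slow/persistent, fast/persistent, fast/erratic),
#: used as default mixture means by :func:`simulate_feature_table`.
#: Rows = classes 1..4, columns = MOTILITY_FEATURE_NAMES.
REFERENCE_CLASS_MEANS = np.array(
    [
        [9.50, 1.46, 0.10, 15.07, 1.85, 2.32, 0.30, 13.87],
        [9.53, 8.93, 0.41, 14.46, 6.10, 8.30, 1.50, 85.10],
        [11.95, 10.57, 0.34, 16.89, 6.55, 56.76, 3.41, 126.31],
        [12.32, 0.82, 0.34, 17.27, 6.04, 21.96, 1.98, 10.10],
    ]
)


# ---------------------------------------------------------------------------
# Persistent random walk
# ---------------------------------------------------------------------------


def prw_msd_theory(t: np.ndarray, speed: float, persistence: float) -> np.ndarray:
    """Closed-form 2-D PRW mean squared displacement (um^2).

    ``<d^2(t)> = 2 S^2 P [t - P (1 - exp(-t/P))]`` with speed S (um/h) the
    root-mean-square speed and persistence P (h) the velocity correlation
    time.
    """
    t = np.asarray(t, dtype=float)
    if np.isinf(persistence):
        return (speed * t) ** 2
    return 2 * speed**2 * persistence * (t - persistence * (1 - np.exp(-t / persistence)))


def simulate_prw_tracks(
    speed: float,
    persistence: float,
    frame_interval: float,
    n_frames: int,
    n_tracks: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate ``n_tracks`` PRW centroid tracks, exactly discretised.

    The velocity is a stationary 2-D Ornstein-Uhlenbeck process with
    ``E|v|^2 = speed^2`` and correlation time ``persistence``; positions are
    its exact integral over each frame interval (position and end-of-step
    velocity are sampled jointly with their exact conditional covariance), so
    the ensemble MSD matches :func:`prw_msd_theory` at every lag without
    time-step bias.

    Parameters
    ----------
    speed : float
        Root-mean-square speed S, um/h (> 0; 0 gives stationary tracks).
    persistence : float
        Velocity correlation time P in hours (> 0; ``np.inf`` gives
        straight-line ballistic tracks).
    frame_interval : float
        Minutes between frames.
    n_frames, n_tracks : int
        Track length (>= 2) and ensemble size.

    Returns
    -------
    (n_tracks, n_frames, 2) ndarray of positions in um, starting at (0, 0).
    """
    if speed < 0:
        raise ValueError("speed must be non-negative")
    if not persistence > 0:
        raise ValueError("persistence must be positive")
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    rng = np.random.default_rng(seed)
    dt = frame_interval / 60.0  # hours
    sigma_v2 = speed**2 / 2.0  # per-component stationary velocity variance

    if np.isinf(persistence):
        lam = 1.0
        drift = dt
        var_x = var_v = cov_xv = 0.0
    else:
        h = dt / persistence
        lam = float(np.exp(-h))
        drift = persistence * (1 - lam)  # position gain from initial velocity
        var_x = sigma_v2 * persistence**2 * (2 * h - 3 + 4 * lam - lam**2)
        var_v = sigma_v2 * (1 - lam**2)
        cov_xv = sigma_v2 * persistence * (1 - lam) ** 2

    # 2x2 Cholesky of the conditional (position, velocity) noise covariance
    a = np.sqrt(max(var_x, 0.0))
    b = cov_xv / a if a > 0 else 0.0
    c = np.sqrt(max(var_v - b**2, 0.0))

    v = rng.normal(0.0, np.sqrt(sigma_v2), size=(n_tracks, 2))
    pos = np.zeros((n_tracks, n_frames, 2))
    for k in range(1, n_frames):
        z1 = rng.standard_normal((n_tracks, 2))
        z2 = rng.standard_normal((n_tracks, 2))
        pos[:, k] = pos[:, k - 1] + v * drift + a * z1
        v = v * lam + b * z1 + c * z2
    return pos


def simulate_prw_track(
    speed: float,
    persistence: float,
    frame_interval: float,
    n_frames: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Single PRW centroid track; see :func:`simulate_prw_tracks`."""
    return simulate_prw_tracks(speed, persistence, frame_interval, n_frames, 1, seed)[0]


# ---------------------------------------------------------------------------
# Movie generator
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic movie generator.

    Defaults emulate the imaging conditions of the motivating dataset
    (12 frames at 10-min intervals, 12-bit intensities, 0.5 um^2 pixels)
    with macrophage-like cells.
    """

    n_frames: int = 12
    frame_interval: float = 10.0  # minutes
    pixel_size: float = 0.707  # um per pixel side (0.5 um^2 pixels)
    image_shape: tuple[int, int] = (448, 448)
    n_cells: int = 8
    speed: float = 10.0  # um/h, RMS
    persistence: float = 2.0  # h
    base_radius: float = 15.0  # um
    #: (angular frequency, amplitude um, rotation rate rad/frame) per mode
    boundary_modes: tuple[tuple[float, float, float], ...] = (
        (2, 2.5, 0.9),
        (3, 1.5, 1.7),
        (5, 0.8, 2.6),
    )
    protrusion_bias: float = 0.0  # signed um of radial growth per interval
    foreground: float = 3000.0
    background: float = 200.0
    noise_sd: float = 100.0
    bit_depth: int = 12
    n_markers: int = 360
    #: optional division event: (cell_id, frame) — that cell splits in two
    division: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        for name in ("frame_interval", "pixel_size", "base_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        amp = sum(m[1] for m in self.boundary_modes)
        shrink = max(0.0, -self.protrusion_bias) * (self.n_frames - 1)
        if self.base_radius - amp - shrink <= 1.0:
            raise ValueError("boundary modes/bias would collapse the cell radius")
        if self.foreground <= self.background:
            raise ValueError("foreground intensity must exceed background")

    @property
    def intensity_max(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def max_radius(self) -> float:
        grow = max(0.0, self.protrusion_bias) * (self.n_frames - 1)
        return self.base_radius + sum(m[1] for m in self.boundary_modes) + grow


@dataclass
class SimulatedMovie:
    """Movie plus all ground truth needed to close the testing loop."""

    frames: np.ndarray  # (T, H, W) uint16 intensities (12-bit range)
    label_masks: np.ndarray  # (T, H, W) int32, 0 = background
    tracks: pd.DataFrame  # frame, cell_id, centroid_row, centroid_col, area_px
    polar_radii: dict[int, np.ndarray]  # cell_id -> (T, M) marker radii, um
    edge_prints: dict[int, EdgePrint]  # cell_id -> true edge print
    events: list[dict]  # division events, if any
    config: SimulationConfig


def _radius_profile(cfg: SimulationConfig, phases: np.ndarray, theta: np.ndarray, t: int):
    """Boundary radius r(theta, t) in um for one cell."""
    r = np.full_like(theta, cfg.base_radius + cfg.protrusion_bias * t, dtype=float)
    for (freq, amp, rate), phi in zip(cfg.boundary_modes, phases):
        r += amp * np.sin(freq * theta + phi + rate * t)
    return r


def _ground_truth_radii(cfg, phases, t, n_fine=1440):
    """True marker radii (um) about the shape's own area centroid at frame t.

    Boundary points are generated from the polar form about the nominal
    centre, shifted to the area centroid, and resampled on the edge-dynamics
    marker grid with the same outermost-crossing rule.
    """
    theta = np.arange(n_fine) * (2 * np.pi / n_fine)
    r = _radius_profile(cfg, phases, theta, t)
    dtheta = 2 * np.pi / n_fine
    area = 0.5 * np.sum(r**2) * dtheta
    cx = np.sum(r**3 * np.cos(theta)) * dtheta / (3 * area)
    cy = np.sum(r**3 * np.sin(theta)) * dtheta / (3 * area)
    # polygon in (row=y, col=x) "pixel" units of 1 um so polar_resample applies
    poly = np.stack([r * np.sin(theta) - cy, r * np.cos(theta) - cx], axis=1)
    pb = polar_resample(poly, (0.0, 0.0), n_markers=cfg.n_markers, pixel_size=1.0, frame=t)
    return pb.radii, np.array([cy, cx])  # offset of centroid from nominal centre, um


def simulate_cell_movie(config: SimulationConfig | None = None, **overrides) -> SimulatedMovie:
    """Render a synthetic movie with full ground truth.

    Cells are placed so that their track bounding discs never overlap (a
    configuration error is raised if the frame cannot accommodate them),
    rendered as constant-foreground star shapes with additive Gaussian noise,
    and clipped to the 12-bit range.

    Returns a :class:`SimulatedMovie`; ``tracks`` holds per-frame ground truth
    (area centroid of the continuous shape, in pixels) and ``edge_prints`` the
    true protrusion/retraction velocities computed from the analytic boundary
    on the same marker grid used by the edge-dynamics module.
    """
    cfg = config or SimulationConfig(**overrides)
    if config is not None and overrides:
        cfg = dataclasses.replace(config, **overrides)
    rng = np.random.default_rng(cfg.seed)
    T, (H, W) = cfg.n_frames, cfg.image_shape
    px = cfg.pixel_size

    tracks_um = simulate_prw_tracks(
        cfg.speed, cfg.persistence, cfg.frame_interval, T, cfg.n_cells, rng
    )
    phases = rng.uniform(0, 2 * np.pi, size=(cfg.n_cells, len(cfg.boundary_modes)))

    # --- placement: non-overlapping track bounding discs, margin to border
    reach = cfg.max_radius + np.max(np.linalg.norm(tracks_um, axis=2), axis=1)  # per cell, um
    margin_px = reach / px + 4
    centers = np.zeros((cfg.n_cells, 2))  # (row, col) px at t=0
    placed = 0
    for i in range(cfg.n_cells):
        lo = margin_px[i]
        if H - 2 * lo <= 0 or W - 2 * lo <= 0:
            raise ValueError("image too small for the configured cells")
        for _ in range(2000):
            cand = np.array([rng.uniform(lo, H - lo), rng.uniform(lo, W - lo)])
            d = np.linalg.norm(centers[:placed] - cand, axis=1) if placed else np.array([np.inf])
            if np.all(d * px > reach[i] + reach[:placed] + 3 if placed else True):
                centers[i] = cand
                placed += 1
                break
        else:
            raise ValueError("could not place cells without overlap; enlarge image_shape")

    # --- division bookkeeping
    div_cell, div_frame = (cfg.division if cfg.division is not None else (None, None))
    events = []
    if div_cell is not None:
        if not (0 < div_frame < T - 1):
            raise ValueError("division frame must be interior to the movie")
        events.append({"frame": int(div_frame), "case": "DIVISION", "parent": int(div_cell)})

    frames = np.zeros((T, H, W), dtype=np.uint16)
    labels = np.zeros((T, H, W), dtype=np.int32)
    rows = []
    polar_truth: dict[int, np.ndarray] = {
        i: np.zeros((T, cfg.n_markers)) for i in range(cfg.n_cells) if i != div_cell
    }

    rr, cc = np.mgrid[0:H, 0:W]
    noise = rng.normal(0.0, cfg.noise_sd, size=(T, H, W)) if cfg.noise_sd > 0 else None

    def paint(img, lab, center_px, radius_fn, label_value):
        rad_px = cfg.max_radius / px + 2
        r0, r1 = int(max(0, center_px[0] - rad_px)), int(min(H, center_px[0] + rad_px + 1))
        c0, c1 = int(max(0, center_px[1] - rad_px)), int(min(W, center_px[1] + rad_px + 1))
        dy = (rr[r0:r1, c0:c1] - center_px[0]) * px
        dx = (cc[r0:r1, c0:c1] - center_px[1]) * px
        rho = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx) % (2 * np.pi)
        inside = rho <= radius_fn(theta)
        img[r0:r1, c0:c1][inside] = cfg.foreground
        lab[r0:r1, c0:c1][inside] = label_value

    next_child = cfg.n_cells
    for t in range(T):
        img = np.full((H, W), cfg.background, dtype=float)
        lab = labels[t]
        for i in range(cfg.n_cells):
            center_px = centers[i] + tracks_um[i, t][::-1] / px  # track (x, y) -> (row, col)
            if i == div_cell and t >= div_frame:
                # two daughters drifting apart along a fixed axis
                sep = (0.8 * 0.6 * cfg.base_radius + 2.0 * (t - div_frame)) / px
                u = np.array([np.sin(phases[i, 0]), np.cos(phases[i, 0])])
                small = 0.6 * cfg.base_radius

                def child_radius(theta, tt=t, ph=phases[i]):
                    return small + 0.3 * sum(
                        a * np.sin(f * theta + p + w * tt)
                        for (f, a, w), p in zip(cfg.boundary_modes, ph)
                    )

                for s, lbl in ((+1, next_child), (-1, next_child + 1)):
                    cpx = center_px + s * sep * u
                    paint(img, lab, cpx, child_radius, lbl + 1)
                    rows.append(
                        dict(frame=t, cell_id=lbl, centroid_row=cpx[0], centroid_col=cpx[1],
                             area_px=np.pi * small**2 / px**2)
                    )
                continue
            gt_radii, offset_um = _ground_truth_radii(cfg, phases[i], t)
            if i != div_cell:
                polar_truth[i][t] = gt_radii
            paint(img, lab, center_px, lambda th, i=i, t=t: _radius_profile(cfg, phases[i], th, t),
                  i + 1)
            centroid_px = center_px + offset_um / px  # offset is (row, col) in um
            rows.append(
                dict(frame=t, cell_id=i, centroid_row=centroid_px[0],
                     centroid_col=centroid_px[1],
                     area_px=float(np.count_nonzero(lab == i + 1)))
            )
        if noise is not None:
            img = img + noise[t]
        frames[t] = np.clip(img, 0, cfg.intensity_max).astype(np.uint16)

    prints = {
        i: edge_print_from_radii(polar_truth[i], cfg.frame_interval, cell_id=i)
        for i in polar_truth
    }
    tracks = pd.DataFrame(rows)
    return SimulatedMovie(
        frames=frames,
        label_masks=labels,
        tracks=tracks,
        polar_radii=polar_truth,
        edge_prints=prints,
        events=events,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Feature-table generator
# ---------------------------------------------------------------------------


def simulate_feature_table(
    class_means: np.ndarray | None = None,
    class_covariances: np.ndarray | float | None = None,
    class_weights: np.ndarray | None = None,
    n_samples: int = 2000,
    seed: int | np.random.Generator = 0,
    feature_names: tuple[str, ...] = MOTILITY_FEATURE_NAMES,
) -> pd.DataFrame:
    """Draw labelled i.i.d. samples from a Gaussian mixture.

    Defaults to the four reference macrophage class means
    (:data:`REFERENCE_CLASS_MEANS`) with a small isotropic covariance
    (sd 0.5 in raw feature units), equal weights.

    Returns a DataFrame with the feature columns plus ``true_class`` (0-based
    component labels).
    """
    rng = np.random.default_rng(seed)
    means = np.atleast_2d(REFERENCE_CLASS_MEANS if class_means is None else class_means)
    k, n = means.shape
    if class_covariances is None:
        class_covariances = 0.25  # sd 0.5 isotropic
    if np.isscalar(class_covariances):
        covs = np.tile(np.eye(n) * float(class_covariances), (k, 1, 1))
    else:
        covs = np.asarray(class_covariances, dtype=float)
        if covs.ndim == 2:
            covs = np.tile(covs, (k, 1, 1))
    if covs.shape != (k, n, n):
        raise ValueError("covariances must broadcast to (k, n, n)")
    w = np.full(k, 1.0 / k) if class_weights is None else np.asarray(class_weights, float)
    if w.shape != (k,) or np.any(w <= 0) or abs(w.sum() - 1) > 1e-9:
        raise ValueError("class weights must be positive and sum to 1")
    for c in covs:
        if np.min(np.linalg.eigvalsh(c)) < -1e-10:
            raise ValueError("covariances must be positive semi-definite")

    labels = rng.choice(k, size=n_samples, p=w)
    x = np.empty((n_samples, n))
    for j in range(k):
        idx = np.flatnonzero(labels == j)
        if idx.size:
            x[idx] = rng.multivariate_normal(means[j], covs[j], size=idx.size,
                                             method="eigh")
    df = pd.DataFrame(x, columns=list(feature_names[:n]) if len(feature_names) >= n
                      else [f"f{i}" for i in range(n)])
    df["true_class"] = labels
    return df


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_movie(movie: SimulatedMovie, outdir: str | Path) -> dict[str, Path]:
    """Write movie TIFF, ground-truth CSV/JSON into ``outdir``; returns paths."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "movie": outdir / "movie.tif",
        "labels": outdir / "labels.tif",
        "tracks": outdir / "truth_tracks.csv",
        "config": outdir / "config.json",
    }
    tifffile.imwrite(paths["movie"], movie.frames)
    tifffile.imwrite(paths["labels"], movie.label_masks.astype(np.uint16))
    movie.tracks.to_csv(paths["tracks"], index=False)
    cfg = dataclasses.asdict(movie.config)
    cfg["image_shape"] = list(cfg["image_shape"])
    cfg["boundary_modes"] = [list(m) for m in cfg["boundary_modes"]]
    paths["config"].write_text(json.dumps(cfg, indent=2))
    return paths
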