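"""Edge dynamics: polar-marker boundary displacement and the "edge print".

A cell's membrane activity is quantified by placing ``M`` equiangular markers
on its segmented boundary, expressed in polar coordinates about the cell's own
centroid.  Between two frames (interval ``tau``) each marker moves radially by
``delta_m = r_m(t + tau) - r_m(t)``; outward movement is a protrusion, inward
movement a retraction.  Per interval the protrusion velocity is the mean
positive displacement per marker per minute and the retraction velocity the
mean negative displacement magnitude:

    p_t = (1 / (M tau)) * sum_m max(delta_m, 0)
    r_t = (1 / (M tau)) * sum_m max(-delta_m, 0)

Concatenating ``p_1..p_{T-1}`` and ``r_1..r_{T-1}`` gives the edge print, a
``2(T-1)``-vector (22 features for a 12-frame movie) that characterises
membrane movement over the whole observation, independent of translation
(the centroid alignment removes whole-cell motion).

Coordinates: boundaries are polygons in image (row, col) pixel coordinates;
internally the polar frame uses x = col, y = row, with marker angles measured
from the +x axis.  Radii are reported in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolarBoundary",
    "EdgePrint",
    "polar_resample",
    "boundary_displacement",
    "edge_print",
    "edge_print_from_radii",
    "marker_displacement_table",
]


@dataclass(frozen=True)
class PolarBoundary:
    """Cell boundary sampled on an equiangular polar grid about the centroid.

    Attributes
    ----------
    angles : (M,) ndarray
        Marker angles in radians, equally spaced on [0, 2*pi).
    radii : (M,) ndarray
        Distance (micrometres) from the aligned centroid to the boundary
        along each marker ray (outermost crossing for non-star shapes).
    frame : int
        Frame index the boundary belongs to.
    """

    angles: np.ndarray
    radii: np.ndarray
    frame: int = 0

    def __post_init__(self) -> None:
        if self.angles.shape != self.radii.shape:
            raise ValueError("angles and radii must have the same shape")
        if np.any(self.radii <= 0):
            raise ValueError("polar radii must be positive")


@dataclass(frozen=True)
class EdgePrint:
    """Protrusion/retraction velocity vectors of one cell.

    ``protrusion[t]`` and ``retraction[t]`` are the velocities (um/min) over
    the interval from frame ``t`` to frame ``t + tau_frames``; both are
    non-negative by construction.
    """

    protrusion: np.ndarray
    retraction: np.ndarray
    tau_minutes: float
    cell_id: int | None = None

    @property
    def vector(self) -> np.ndarray:
        """Concatenated feature vector (all protrusions, then retractions)."""
        return np.concatenate([self.protrusion, self.retraction])

    @property
    def n_features(self) -> int:
        return self.protrusion.size + self.retraction.size


def _point_in_polygon(point: np.ndarray, polygon: np.ndarray) -> bool:
    """Even-odd rule point-in-polygon test. ``polygon`` is (k, 2) in (x, y)."""
    x, y = point
    xs, ys = polygon[:, 0], polygon[:, 1]
    xe, ye = np.roll(xs, -1), np.roll(ys, -1)
    crosses = (ys > y) != (ye > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_at_y = xs + (y - ys) / (ye - ys) * (xe - xs)
    return bool(np.sum(crosses & (x < x_at_y)) % 2)


def _ray_radii(polygon_xy: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Outermost intersection distance of each ray with a closed polygon.

    ``polygon_xy`` is (k, 2) with the centroid at the origin.  For each angle
    the ray ``t * (cos a, sin a), t > 0`` is intersected with every polygon
    edge; the largest valid ``t`` is taken, so protruding tips of non-star
    shapes are preserved.
    """
    p1 = polygon_xy
    p2 = np.roll(polygon_xy, -1, axis=0)
    e = p2 - p1  # (k, 2)
    d = np.stack([np.cos(angles), np.sin(angles)], axis=1)  # (M, 2)

    # Solve t*d = p1 + u*e per (ray, edge) via 2-D cross products.
    denom = d[:, None, 0] * e[None, :, 1] - d[:, None, 1] * e[None, :, 0]
    cross_p1e = p1[None, :, 0] * e[None, :, 1] - p1[None, :, 1] * e[None, :, 0]
    cross_p1d = p1[None, :, 0] * d[:, None, 1] - p1[None, :, 1] * d[:, None, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross_p1e / denom
        u = cross_p1d / denom
    eps = 1e-12
    valid = (np.abs(denom) > eps) & (t > eps) & (u >= -1e-9) & (u < 1 + 1e-9)
    t = np.where(valid, t, -np.inf)
    radii = t.max(axis=1)
    if np.any(~np.isfinite(radii)):
        raise ValueError("some rays do not intersect the boundary polygon")
    return radii


def polar_resample(
    boundary: np.ndarray,
    centroid: tuple[float, float],
    n_markers: int = 360,
    pixel_size: float = 1.0,
    frame: int = 0,
) -> PolarBoundary:
    """Resample a boundary polygon onto ``n_markers`` equiangular rays.

    Parameters
    ----------
    boundary : (k, 2) ndarray
        Closed simple polygon in (row, col) pixel coordinates (first point
        need not be repeated at the end).
    centroid : (row, col)
        Alignment centre; must lie inside the polygon.
    n_markers : int
        Number of markers M (>= 8).
    pixel_size : float
        Micrometres per pixel side; radii are returned in micrometres.
    """
    if n_markers < 8:
        raise ValueError("n_markers must be at least 8")
    boundary = np.asarray(boundary, dtype=float)
    if boundary.ndim != 2 or boundary.shape[1] != 2 or boundary.shape[0] < 3:
        raise ValueError("boundary must be a (k>=3, 2) polygon")
    # drop a duplicated closing vertex
    if np.allclose(boundary[0], boundary[-1]):
        boundary = boundary[:-1]
    cr, cc = centroid
    poly_xy = np.stack([boundary[:, 1] - cc, boundary[:, 0] - cr], axis=1)
    if not _point_in_polygon(np.zeros(2), poly_xy):
        raise ValueError("centroid lies outside the boundary polygon")
    angles = np.arange(n_markers) * (2 * np.pi / n_markers)
    radii = _ray_radii(poly_xy, angles) * pixel_size
    return PolarBoundary(angles=angles, radii=radii, frame=frame)


def boundary_displacement(polar_t: PolarBoundary, polar_t1: PolarBoundary) -> np.ndarray:
    """Signed per-marker radial displacement (um) between two aligned boundaries.

    Positive entries are protrusions, negative entries retractions.  Both
    boundaries must share the same marker grid.
    """
    if polar_t.angles.shape != polar_t1.angles.shape or not np.allclose(
        polar_t.angles, polar_t1.angles
    ):
        raise ValueError("boundaries are sampled on different marker grids")
    return polar_t1.radii - polar_t.radii


def edge_print_from_radii(
    radii: np.ndarray,
    frame_interval: float,
    tau_frames: int = 1,
    normalize: bool = True,
    cell_id: int | None = None,
) -> EdgePrint:
    """Edge print from a (T, M) array of per-frame marker radii (um).

    Parameters
    ----------
    radii : (T, M) ndarray
        Marker radii for all frames of one cell, centroid-aligned.
    frame_interval : float
        Minutes between consecutive frames.
    tau_frames : int
        Sampling interval tau in frames (default: adjacent frames).
    normalize : bool
        If True (default) displacements are averaged over markers, giving a
        per-marker velocity in um/min comparable across choices of M.  With
        False the marker sum (total boundary displacement per minute) is
        returned instead.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 2 or radii.shape[0] < tau_frames + 1:
        raise ValueError("need at least tau_frames + 1 frames of radii")
    tau_min = tau_frames * frame_interval
    delta = radii[tau_frames:] - radii[:-tau_frames]  # (T - tau, M)
    scale = delta.shape[1] * tau_min if normalize else tau_min
    prot = np.maximum(delta, 0.0).sum(axis=1) / scale
    retr = np.maximum(-delta, 0.0).sum(axis=1) / scale
    return EdgePrint(protrusion=prot, retraction=retr, tau_minutes=tau_min, cell_id=cell_id)


def edge_print(
    boundaries: list[PolarBoundary],
    frame_interval: float,
    tau_frames: int = 1,
    normalize: bool = True,
    cell_id: int | None = None,
) -> EdgePrint:
    """Edge print of one cell from its per-frame polar boundaries.

    A 12-frame track yields 11 protrusion and 11 retraction features (22 in
    total) at the default ``tau_frames=1``.
    """
    if len(boundaries) < tau_frames + 1:
        raise ValueError("track too short for the requested tau")
    m = boundaries[0].angles.size
    for b in boundaries:
        if b.angles.size != m:
            raise ValueError("all frames must use the same number of markers")
    radii = np.stack([b.radii for b in boundaries])
    return edge_print_from_radii(
        radii, frame_interval, tau_frames=tau_frames, normalize=normalize, cell_id=cell_id
    )


def marker_displacement_table(boundaries: list[PolarBoundary], tau_frames: int = 1):
    """Long-format per-marker displacement table (for angle-vs-difference plots).

    Returns a DataFrame with columns ``frame``, ``angle_rad``,
    ``displacement_um`` where ``frame`` indexes the start of each interval.
    """
    import pandas as pd

    rows = []
    for t in range(len(boundaries) - tau_frames):
        delta = boundary_displacement(boundaries[t], boundaries[t + tau_frames])
        rows.append(
            pd.DataFrame(
                {
                    "frame": t,
                    "angle_rad": boundaries[t].angles,
                    "displacement_um": delta,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
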