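"""Per-frame cell segmentation: two-phase piecewise-constant energy + watershed.

Cells are bright objects on a relatively uniform dark background.  A frame is
segmented by minimising the two-phase piecewise-constant (active contours
without edges) energy

    E(m, c1, c2) = sum_fg (I - c1)^2 + sum_bg (I - c2)^2 + mu * Len(m)

over binary labelings ``m`` and phase means ``c1, c2``, where ``Len`` is the
(anisotropic, 4-neighbour) contour length and ``mu`` the length weight — the
only regularisation term.  Minimisation is exact block coordinate descent:
checkerboard pixel sweeps alternate with closed-form mean updates, so the
energy is non-increasing at every step and iteration stops when its relative
change falls below ``tol``.  Touching cells in the resulting foreground are
split by a marker-controlled watershed seeded at regional maxima of the
smoothed distance transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import find_contours, regionprops
from skimage.morphology import h_maxima, local_maxima
from skimage.segmentation import watershed

__all__ = [
    "ChanVeseResult",
    "CellRegion",
    "chan_vese_binary",
    "split_touching",
    "extract_regions",
    "segment_frame",
]


@dataclass
class ChanVeseResult:
    """Binary segmentation with its energy trajectory."""

    mask: np.ndarray  # bool, foreground = brighter phase
    energies: np.ndarray  # total energy after each sweep
    converged: bool
    flat_image: bool = False  # constant input: empty mask, warning issued

    def __bool__(self) -> bool:  # pragma: no cover - convenience only
        return bool(self.mask.any())


@dataclass
class CellRegion:
    """One segmented cell in one frame."""

    label: int
    centroid: tuple[float, float]  # (row, col), geometric (intensity-unweighted)
    area: float  # pixels
    mean_intensity: float
    boundary: np.ndarray  # (k, 2) ordered closed polygon, (row, col)
    coords: np.ndarray | None = None  # (area, 2) int pixel coordinates


def _neighbor_sum(m: np.ndarray) -> np.ndarray:
    """Number of 4-neighbours of each pixel currently labelled foreground."""
    s = np.zeros(m.shape, dtype=np.int32)
    s[1:, :] += m[:-1, :]
    s[:-1, :] += m[1:, :]
    s[:, 1:] += m[:, :-1]
    s[:, :-1] += m[:, 1:]
    return s


def _energy(img, m, c1, c2, mu):
    fit = np.where(m, (img - c1) ** 2, (img - c2) ** 2).sum()
    horiz = np.count_nonzero(m[:, 1:] != m[:, :-1])
    vert = np.count_nonzero(m[1:, :] != m[:-1, :])
    return fit + mu * (horiz + vert)


def chan_vese_binary(
    frame: np.ndarray,
    length_weight: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ChanVeseResult:
    """Two-phase segmentation of a frame into bright foreground / dark background.

    The image is normalised to unit dynamic range, so ``length_weight`` is the
    contour-length penalty relative to a squared intensity contrast of 1.

    Parameters
    ----------
    frame : 2-D ndarray
        Intensities (12-bit range or any non-negative scale), >= 16x16 px.
    length_weight : float
        mu >= 0; larger values smooth the contour and suppress specks.
    tol : float
        Stop when the relative energy decrease over a sweep is below this.
    max_iter : int
        Maximum number of full checkerboard sweeps.

    Returns
    -------
    ChanVeseResult
        ``mask`` is True on the brighter phase.  A constant image yields an
        empty mask with ``flat_image=True`` and a warning.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2 or min(img.shape) < 16:
        raise ValueError("frame must be a 2-D image of at least 16x16 pixels")
    if length_weight < 0:
        raise ValueError("length_weight must be non-negative")
    lo, hi = img.min(), img.max()
    if hi - lo <= 0:
        warnings.warn("constant image: returning empty foreground", stacklevel=2)
        return ChanVeseResult(
            mask=np.zeros(img.shape, bool), energies=np.array([0.0]),
            converged=True, flat_image=True,
        )
    img = (img - lo) / (hi - lo)
    mu = length_weight

    m = img > img.mean()
    checker = (np.add.outer(np.arange(img.shape[0]), np.arange(img.shape[1])) % 2).astype(bool)
    energies = []
    converged = False
    for _ in range(max_iter):
        c1 = img[m].mean() if m.any() else img.mean()
        c2 = img[~m].mean() if (~m).any() else img.mean()
        d1 = (img - c1) ** 2
        d2 = (img - c2) ** 2
        nb = _neighbor_sum(np.ones_like(m))  # valid-neighbour counts (2..4)
        for parity in (checker, ~checker):
            s = _neighbor_sum(m)
            # energy contribution of this pixel: fg -> d1 + mu*(nb - s); bg -> d2 + mu*s
            prefer_fg = d1 + mu * (nb - s) < d2 + mu * s
            m = np.where(parity, prefer_fg, m)
        e = _energy(img, m, img[m].mean() if m.any() else c1,
                    img[~m].mean() if (~m).any() else c2, mu)
        energies.append(e)
        if len(energies) > 1:
            prev = energies[-2]
            if prev - e <= tol * max(prev, 1e-30):
                converged = True
                break
    # foreground = brighter phase
    if m.any() and (~m).any() and img[m].mean() < img[~m].mean():
        m = ~m
    return ChanVeseResult(mask=m, energies=np.asarray(energies), converged=converged)


def split_touching(
    mask: np.ndarray,
    smoothing_sigma: float = 2.0,
    marker_depth: float = 2.0,
) -> np.ndarray:
    """Split touching cells by marker-controlled watershed on the distance map.

    Markers are the regional maxima of the Gaussian-smoothed Euclidean
    distance transform of the foreground, with maxima of prominence below
    ``marker_depth`` pixels suppressed (h-maxima) so that shallow bumps of a
    single lobed cell do not seed spurious splits while genuine necks between
    touching cells — whose saddle is several pixels deep — still do.  Each
    connected component with a single marker passes through unchanged.  The
    union of foreground pixels is preserved exactly.

    Returns an int32 label image with contiguous labels 1..L (0 = background).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    smooth = ndi.gaussian_filter(dist, smoothing_sigma)
    if marker_depth > 0:
        peaks = h_maxima(smooth, marker_depth) & mask
    else:
        peaks = local_maxima(smooth, allow_borders=True) & mask
    markers, n_markers = ndi.label(peaks)
    if n_markers == 0:  # degenerate (e.g. 1-px-wide mask); fall back to components
        labels, _ = ndi.label(mask)
        return labels.astype(np.int32)
    labels = watershed(-smooth, markers, mask=mask)
    # relabel contiguously
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def _outer_boundary(
    region_mask: np.ndarray, origin: tuple[int, int], smooth_window: int = 5
) -> np.ndarray:
    """Ordered closed outer boundary of a binary region, (row, col) sub-pixel.

    The marching-squares contour is lightly smoothed by a circular moving
    average (``smooth_window`` vertices) to remove the staircase quantisation
    of binary masks, which otherwise biases boundary length upward by ~7%;
    the induced inward shift is O(R * dtheta^2), far below a pixel for
    cell-sized regions.
    """
    padded = np.pad(region_mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    contour = max(contours, key=len) - 1.0  # unpad
    if smooth_window > 1 and len(contour) > 2 * smooth_window:
        closed = contour[:-1] if np.allclose(contour[0], contour[-1]) else contour
        kernel = np.ones(smooth_window) / smooth_window
        sm = np.column_stack(
            [
                np.convolve(np.concatenate([c[-smooth_window:], c, c[:smooth_window]]),
                            kernel, mode="same")[smooth_window:-smooth_window]
                for c in (closed[:, 0], closed[:, 1])
            ]
        )
        contour = sm
    contour = contour + np.asarray(origin, dtype=float)
    # canonical orientation: positive signed area in (x=col, y=row)
    x, y = contour[:, 1], contour[:, 0]
    signed = 0.5 * np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])
    if signed < 0:
        contour = contour[::-1]
    return contour


def extract_regions(
    label_mask: np.ndarray,
    frame: np.ndarray,
    min_area: int = 50,
    keep_coords: bool = True,
) -> list[CellRegion]:
    """Per-label centroid, area, mean intensity and ordered outer boundary.

    Labels smaller than ``min_area`` pixels are dropped (noise specks at the
    working pixel size).
    """
    if label_mask.shape != frame.shape:
        raise ValueError("label mask and frame shapes differ")
    regions = []
    for rp in regionprops(label_mask.astype(np.int32), intensity_image=frame):
        if rp.area < min_area:
            continue
        r0, c0, _, _ = rp.bbox
        boundary = _outer_boundary(rp.image, (r0, c0))
        regions.append(
            CellRegion(
                label=int(rp.label),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                area=float(rp.area),
                mean_intensity=float(rp.intensity_mean),
                boundary=boundary,
                coords=rp.coords if keep_coords else None,
            )
        )
    return regions


def segment_frame(
    frame: np.ndarray,
    length_weight: float = 0.1,
    min_area: int = 50,
    smoothing_sigma: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, list[CellRegion]]:
    """Full single-frame segmentation: binary energy minimisation, watershed
    splitting, region extraction.  Returns (label mask, regions)."""
    cv = chan_vese_binary(frame, length_weight=length_weight, tol=tol, max_iter=max_iter)
    labels = split_touching(cv.mask, smoothing_sigma=smoothing_sigma)
    return labels, extract_regions(labels, frame, min_area=min_area)
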