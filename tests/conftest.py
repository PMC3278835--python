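"""Shared fixtures: one synthetic movie and its segmentation/tracking, reused
across modules (session scope keeps the suite fast)."""

import numpy as np
import pytest

from morphodyn import segmentation as seg
from morphodyn import tracking as trk
from morphodyn.simulate import SimulationConfig, simulate_cell_movie


@pytest.fixture(scope="session")
def movie():
    """Default-condition synthetic movie (8 cells, 12 frames) with ground truth."""
    return simulate_cell_movie(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def segmented(movie):
    """Per-frame (label mask, regions) for the shared movie."""
    out = [seg.segment_frame(f) for f in movie.frames]
    return [o[0] for o in out], [o[1] for o in out]


@pytest.fixture(scope="session")
def tracked(segmented):
    """(tracks, events) built from the shared movie's regions."""
    _, regions = segmented
    return trk.build_tracks(regions)


@pytest.fixture(scope="session")
def gt_match(movie, tracked):
    """Map track -> ground-truth cell id via frame-0 centroid proximity."""
    tracks, _ = tracked
    g0 = movie.tracks[movie.tracks.frame == 0]
    mapping = {}
    for tr in tracks:
        d = np.hypot(
            g0.centroid_row - tr.regions[0].centroid[0],
            g0.centroid_col - tr.regions[0].centroid[1],
        )
        mapping[tr.cell_id] = int(g0.cell_id.iloc[np.argmin(d.values)])
    return mapping


def disc_image(shape=(100, 100), center=(50, 50), radius=20.0, fg=3000.0, bg=200.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, bg)
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2] = fg
    return img
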