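"""Frame-to-frame cell linking with division / over-segmentation heuristics.

Segmented cells in adjacent frames are matched by a spatiotemporal cost that
mixes position, size and intensity similarity; the global assignment is the
minimum-total-cost bipartite matching, gated by centroid distance (no overlap
of boundaries between frames is assumed).  Four cases arise per decision:

* ``MATCH``    — one-to-one link,
* ``LOST``     — no counterpart (cell left the field or appeared),
* ``DIVISION`` — one cell matches two in the next frame and both children
  have their own matches one frame later,
* ``OVERSEG``  — a one-to-two (or two-to-one) link whose extra fragment has
  no independent future: the fragments are merged back.

Division/over-segmentation disambiguation therefore needs three consecutive
frames; at the final frame the conservative default is a plain match, logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .segmentation import CellRegion

__all__ = [
    "MatchCase",
    "FrameMatch",
    "Track",
    "match_frames",
    "resolve_ambiguities",
    "build_tracks",
    "tracks_to_dataframe",
]

#: default feature weights (position, size, intensity); position dominates at
#: 10-min sampling where displacement is the most informative cue
DEFAULT_WEIGHTS = (0.5, 0.25, 0.25)
_UNMATCHED = 1.5  # cost of leaving a region unmatched (> max gated cost of 1)


class MatchCase(str, Enum):
    MATCH = "MATCH"
    LOST = "LOST"
    DIVISION = "DIVISION"
    OVERSEG = "OVERSEG"


@dataclass
class FrameMatch:
    """Assignment between the regions of two consecutive frames.

    ``pairs`` holds (index_t, index_t1, cost); ``lost`` / ``new`` are indices
    unmatched in frame t / t+1; ``secondary`` maps an index in frame t to
    additional frame-t+1 candidates whose cost is within the ambiguity ratio
    of its assigned match (and vice versa for ``secondary_rev``).
    """

    pairs: list[tuple[int, int, float]]
    lost: list[int]
    new: list[int]
    secondary: dict[int, list[tuple[int, float]]] = field(default_factory=dict)
    secondary_rev: dict[int, list[tuple[int, float]]] = field(default_factory=dict)

    def partner_of(self, i: int) -> int | None:
        for a, b, _ in self.pairs:
            if a == i:
                return b
        return None

    def partner_rev(self, j: int) -> int | None:
        for a, b, _ in self.pairs:
            if b == j:
                return a
        return None


def _cost_matrix(regions_a, regions_b, weights, gate_distance):
    w_pos, w_size, w_int = weights
    ca = np.array([r.centroid for r in regions_a])
    cb = np.array([r.centroid for r in regions_b])
    aa = np.array([r.area for r in regions_a])
    ab = np.array([r.area for r in regions_b])
    ia = np.array([r.mean_intensity for r in regions_a])
    ib = np.array([r.mean_intensity for r in regions_b])
    dist = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    max_area = np.maximum(aa[:, None], ab[None, :])
    max_int = np.maximum(np.abs(ia)[:, None], np.abs(ib)[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = (
            w_pos * dist / gate_distance
            + w_size * np.abs(aa[:, None] - ab[None, :]) / np.where(max_area > 0, max_area, 1)
            + w_int * np.abs(ia[:, None] - ib[None, :]) / np.where(max_int > 0, max_int, 1)
        )
    cost[dist > gate_distance] = np.inf
    return cost


def match_frames(
    regions_t: list[CellRegion],
    regions_t1: list[CellRegion],
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    gate_distance: float = 50.0,
    ambiguity_ratio: float = 1.5,
) -> FrameMatch:
    """Minimum-cost matching of regions between two frames.

    cost(a, b) = w_pos * ||centroid_a - centroid_b|| / gate
               + w_size * |area_a - area_b| / max(area_a, area_b)
               + w_int  * |int_a - int_b| / max(int_a, int_b)

    Pairs whose centroid distance exceeds ``gate_distance`` (pixels) are
    excluded.  The one-to-many candidate structure keeps, per region, any
    further gated counterpart whose cost is within ``ambiguity_ratio`` times
    its assigned cost — the raw material for division / over-segmentation
    resolution.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    if gate_distance <= 0:
        raise ValueError("gate_distance must be positive")
    na, nb = len(regions_t), len(regions_t1)
    if na == 0 or nb == 0:
        return FrameMatch(pairs=[], lost=list(range(na)), new=list(range(nb)))

    cost = _cost_matrix(regions_t, regions_t1, w, gate_distance)
    big = 10.0 * _UNMATCHED
    padded = np.full((na + nb, na + nb), big)
    padded[:na, :nb] = np.where(np.isfinite(cost), cost, big)
    padded[:na, nb:] = np.where(np.eye(na, dtype=bool), _UNMATCHED, big)
    padded[na:, :nb] = np.where(np.eye(nb, dtype=bool), _UNMATCHED, big)
    padded[na:, nb:] = 0.0
    rows, cols = linear_sum_assignment(padded)

    pairs, lost, new = [], [], []
    assigned_b = set()
    for r, c in zip(rows, cols):
        if r < na and c < nb and np.isfinite(cost[r, c]):
            pairs.append((int(r), int(c), float(cost[r, c])))
            assigned_b.add(int(c))
        elif r < na and (c >= nb or not np.isfinite(cost[r, c])):
            lost.append(int(r))
    new = [j for j in range(nb) if j not in assigned_b]

    secondary: dict[int, list[tuple[int, float]]] = {}
    secondary_rev: dict[int, list[tuple[int, float]]] = {}
    for a, b, c0 in pairs:
        cut = ambiguity_ratio * max(c0, 1e-6)
        extra = [
            (int(j), float(cost[a, j]))
            for j in range(nb)
            if j != b and np.isfinite(cost[a, j]) and cost[a, j] <= cut
        ]
        if extra:
            secondary[a] = sorted(extra, key=lambda x: x[1])
        extra_rev = [
            (int(i), float(cost[i, b]))
            for i in range(na)
            if i != a and np.isfinite(cost[i, b]) and cost[i, b] <= cut
        ]
        if extra_rev:
            secondary_rev[b] = sorted(extra_rev, key=lambda x: x[1])
    return FrameMatch(pairs=pairs, lost=lost, new=new,
                      secondary=secondary, secondary_rev=secondary_rev)


def resolve_ambiguities(match_01: FrameMatch, match_12: FrameMatch) -> list[dict]:
    """Classify ambiguous links of the first frame pair using the second.

    A one-to-two link ``a -> {b1 (assigned), b2 (unmatched candidate)}`` is a
    DIVISION iff both b1 and b2 have their own assigned matches into the third
    frame; otherwise it is an OVERSEG of the middle frame and b1, b2 should be
    merged.  A two-to-one link ``{a1 (assigned), a2 (lost candidate)} -> b``
    is symmetrically an OVERSEG of the first frame.

    Returns decision dicts: ``{"case": MatchCase, "parent": index in frame t,
    "children": indices in frame t+1}`` (or ``"fragments"`` for first-frame
    over-segmentation).
    """
    decisions = []
    new_set = set(match_01.new)
    lost_set = set(match_01.lost)
    for a, extras in match_01.secondary.items():
        b1 = match_01.partner_of(a)
        cands = [j for j, _ in extras if j in new_set]
        if b1 is None or not cands:
            continue
        b2 = cands[0]
        if match_12.partner_of(b1) is not None and match_12.partner_of(b2) is not None:
            decisions.append({"case": MatchCase.DIVISION, "parent": a, "children": [b1, b2]})
        else:
            decisions.append({"case": MatchCase.OVERSEG, "parent": a, "children": [b1, b2]})
        new_set.discard(b2)
    for b, extras in match_01.secondary_rev.items():
        a1 = match_01.partner_rev(b)
        cands = [i for i, _ in extras if i in lost_set]
        if a1 is None or not cands:
            continue
        decisions.append(
            {"case": MatchCase.OVERSEG, "parent": b, "fragments": [a1, cands[0]],
             "frame_side": "t"}
        )
        lost_set.discard(cands[0])
    return decisions


def merge_regions(r1: CellRegion, r2: CellRegion) -> CellRegion:
    """Union of two regions (used to undo over-segmentation)."""
    area = r1.area + r2.area
    cr = (r1.centroid[0] * r1.area + r2.centroid[0] * r2.area) / area
    cc = (r1.centroid[1] * r1.area + r2.centroid[1] * r2.area) / area
    mean_int = (r1.mean_intensity * r1.area + r2.mean_intensity * r2.area) / area
    coords = None
    boundary = r1.boundary if r1.area >= r2.area else r2.boundary
    if r1.coords is not None and r2.coords is not None:
        from .segmentation import _outer_boundary

        coords = np.vstack([r1.coords, r2.coords])
        origin = coords.min(axis=0)
        extent = coords.max(axis=0) - origin + 1
        mini = np.zeros(extent, dtype=bool)
        mini[coords[:, 0] - origin[0], coords[:, 1] - origin[1]] = True
        boundary = _outer_boundary(mini, tuple(origin))
    return CellRegion(
        label=min(r1.label, r2.label), centroid=(cr, cc), area=area,
        mean_intensity=mean_int, boundary=boundary, coords=coords,
    )


@dataclass
class Track:
    """One cell's per-frame records over a contiguous frame range."""

    cell_id: int
    start_frame: int
    regions: list[CellRegion]
    parent: int | None = None

    @property
    def frames(self) -> list[int]:
        return list(range(self.start_frame, self.start_frame + len(self.regions)))

    def is_complete(self, n_frames: int) -> bool:
        return self.start_frame == 0 and len(self.regions) == n_frames

    def centroids(self) -> np.ndarray:
        return np.array([r.centroid for r in self.regions])


def build_tracks(
    frames_regions: list[list[CellRegion]],
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    gate_distance: float = 50.0,
    ambiguity_ratio: float = 1.5,
    complete_only: bool = True,
    resolve: bool = True,
) -> tuple[list[Track], list[dict]]:
    """Chain frame-pair matchings into tracks.

    Over-segmented fragments in a middle frame are merged back before
    chaining; a division closes the parent track and opens two child tracks
    (so ``complete_only`` excludes divided lineages, keeping only cells
    present over the entire observation).

    Returns (tracks, event log).
    """
    n_frames = len(frames_regions)
    if n_frames < 2:
        raise ValueError("need at least two frames")
    regions = [list(fr) for fr in frames_regions]
    alive = [[True] * len(fr) for fr in regions]
    events: list[dict] = []

    def compute_match(t: int) -> FrameMatch:
        ia = [i for i in range(len(regions[t])) if alive[t][i]]
        ib = [j for j in range(len(regions[t + 1])) if alive[t + 1][j]]
        m = match_frames([regions[t][i] for i in ia], [regions[t + 1][j] for j in ib],
                         weights, gate_distance, ambiguity_ratio)
        remap_a = {k: ia[k] for k in range(len(ia))}
        remap_b = {k: ib[k] for k in range(len(ib))}
        return FrameMatch(
            pairs=[(remap_a[a], remap_b[b], c) for a, b, c in m.pairs],
            lost=[remap_a[i] for i in m.lost],
            new=[remap_b[j] for j in m.new],
            secondary={remap_a[a]: [(remap_b[j], c) for j, c in v]
                       for a, v in m.secondary.items()},
            secondary_rev={remap_b[b]: [(remap_a[i], c) for i, c in v]
                           for b, v in m.secondary_rev.items()},
        )

    # --- chain frame pairs sequentially, repairing as we go
    tracks: list[Track] = []
    active: dict[int, Track] = {}
    next_id = 0
    for i in range(len(regions[0])):
        active[i] = Track(cell_id=next_id, start_frame=0, regions=[regions[0][i]])
        next_id += 1
        tracks.append(active[i])

    for t in range(n_frames - 1):
        m_t = compute_match(t)
        divisions: dict[int, list[int]] = {}
        if resolve and t + 1 < n_frames - 1:
            m_t1 = compute_match(t + 1)
            redo = False
            for d in resolve_ambiguities(m_t, m_t1):
                if d["case"] is MatchCase.OVERSEG and "children" in d:
                    b1, b2 = d["children"]
                    regions[t + 1][b1] = merge_regions(regions[t + 1][b1],
                                                       regions[t + 1][b2])
                    alive[t + 1][b2] = False
                    events.append({"frame": t + 1, "case": "OVERSEG", "merged": [b1, b2]})
                    redo = True
                elif d["case"] is MatchCase.OVERSEG and "fragments" in d:
                    a1, a2 = d["fragments"]
                    tr1, tr2 = active.get(a1), active.get(a2)
                    if tr1 is not None and tr2 is not None and len(tr1.regions) == 1 \
                            and len(tr2.regions) == 1 and tr1.start_frame == tr2.start_frame:
                        merged = merge_regions(regions[t][a1], regions[t][a2])
                        regions[t][a1] = merged
                        tr1.regions[-1] = merged
                        alive[t][a2] = False
                        tracks.remove(tr2)
                        del active[a2]
                        events.append({"frame": t, "case": "OVERSEG", "merged": [a1, a2]})
                        redo = True
                    else:  # fragments with distinct histories: keep both, log
                        events.append({"frame": t, "case": "OVERSEG",
                                       "unmerged": [a1, a2],
                                       "note": "fragments have independent histories"})
                elif d["case"] is MatchCase.DIVISION:
                    divisions[d["parent"]] = d["children"]
                    events.append({"frame": t + 1, "case": "DIVISION",
                                   "parent": d["parent"], "children": d["children"]})
            if redo:
                m_t = compute_match(t)
        elif resolve:
            for a, extras in m_t.secondary.items():
                if any(j in m_t.new for j, _ in extras):
                    events.append({"frame": t, "case": "AMBIGUOUS_FINAL", "region": a,
                                   "note": "no third frame; kept nearest match"})

        nxt: dict[int, Track] = {}
        linked_b: set[int] = set()
        for a, b, _ in m_t.pairs:
            if a not in active:
                continue
            if a in divisions:
                for child in divisions[a]:
                    tr = Track(cell_id=next_id, start_frame=t + 1,
                               regions=[regions[t + 1][child]],
                               parent=active[a].cell_id)
                    next_id += 1
                    tracks.append(tr)
                    nxt[child] = tr
                    linked_b.add(child)
                continue
            tr = active[a]
            tr.regions.append(regions[t + 1][b])
            nxt[b] = tr
            linked_b.add(b)
        for j in m_t.new:
            if j not in linked_b:
                tr = Track(cell_id=next_id, start_frame=t + 1,
                           regions=[regions[t + 1][j]])
                next_id += 1
                tracks.append(tr)
                nxt[j] = tr
        active = nxt

    if complete_only:
        tracks = [tr for tr in tracks if tr.is_complete(n_frames)]
    return tracks, events


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks to the inter-stage CSV contract."""
    rows = []
    for tr in tracks:
        for f, r in zip(tr.frames, tr.regions):
            rows.append(
                dict(track_id=tr.cell_id, frame=f, centroid_row=r.centroid[0],
                     centroid_col=r.centroid[1], area=r.area,
                     mean_intensity=r.mean_intensity)
            )
    return pd.DataFrame(rows, columns=["track_id", "frame", "centroid_row",
                                       "centroid_col", "area", "mean_intensity"])
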