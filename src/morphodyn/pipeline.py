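"""End-to-end orchestration: movie -> masks -> tracks -> features -> classes.

Each stage writes a plain-text artifact (CSV/JSON) into the run directory and
can be re-entered from any intermediate file; all stochastic stages draw
their seeds from one root seed through named substreams, so partial reruns
reproduce the full run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlation as corr
from . import edge as edgemod
from . import motility as motmod
from . import profiling as prof
from . import segmentation as seg
from . import simulate as sim
from . import tracking as trk

__all__ = ["RunConfig", "run_pipeline", "make_demo"]


@dataclass
class RunConfig:
    """Serialisable configuration of a full pipeline run."""

    input_movie: str | None = None  # multi-page TIFF
    input_tracks: str | None = None  # tracks CSV entry point (skips imaging)
    outdir: str = "morphodyn_run"
    pixel_size: float = 0.707  # um per pixel side
    frame_interval: float = 10.0  # minutes
    # segmentation
    length_weight: float = 0.1
    min_area: int = 50
    smoothing_sigma: float = 2.0
    # tracking
    match_weights: tuple[float, float, float] = trk.DEFAULT_WEIGHTS
    gate_distance: float = 50.0
    complete_only: bool = True
    # edge dynamics
    n_markers: int = 360
    tau_frames: int = 1
    # profiling
    k_range: tuple[int, int] = (2, 10)
    edge_k_range: tuple[int, int] = (2, 6)
    kmeans_sample_frac: float = 0.10
    kmeans_iter: int = 1000
    standardize: bool = True
    # correlation
    alpha: float = 0.05
    response: str = "speed_um_per_h"
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        for k in ("match_weights", "k_range", "edge_k_range"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def _substream(root_seed: int, name: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the root seed."""
    h = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages in order; returns the run directory.

    Stages: segmentation (per frame), tracking, motility features, edge
    prints, class profiling (GMM + MDL, then two-phase K-means on edge prints
    within each class), correlation/factor reports.  Zero complete tracks
    halt the pipeline with an explanatory error.  Stages whose sample size is
    too small for a statistical step are skipped and logged, not failed.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name, **counts):
        log.append({"stage": name, "elapsed_s": round(time.time() - t0, 3), **counts})

    (outdir / "config.json").write_text(config.to_json())

    tracks_df: pd.DataFrame
    boundaries_by_track: dict[int, list] = {}

    if config.input_tracks is not None:
        tracks_df = pd.read_csv(config.input_tracks)
        stage("load_tracks", n_rows=len(tracks_df), n_tracks=tracks_df["track_id"].nunique())
        n_frames = int(tracks_df["frame"].max()) + 1
    elif config.input_movie is not None:
        import tifffile

        try:
            frames = tifffile.imread(config.input_movie)
        except Exception as exc:  # corrupt/unreadable input: no partial outputs
            raise PipelineError(f"cannot read movie: {exc}") from exc
        if frames.ndim == 2:
            frames = frames[None]
        n_frames = frames.shape[0]
        regions_per_frame = []
        labels_stack = np.zeros(frames.shape, dtype=np.uint16)
        for t in range(n_frames):
            labels, regions = seg.segment_frame(
                frames[t], length_weight=config.length_weight,
                min_area=config.min_area, smoothing_sigma=config.smoothing_sigma,
            )
            labels_stack[t] = labels
            regions_per_frame.append(regions)
        import tifffile as tf

        tf.imwrite(outdir / "masks.tif", labels_stack)
        regions_rows = [
            dict(frame=t, label=r.label, centroid_row=r.centroid[0],
                 centroid_col=r.centroid[1], area=r.area, mean_intensity=r.mean_intensity)
            for t, regs in enumerate(regions_per_frame) for r in regs
        ]
        pd.DataFrame(regions_rows).to_csv(outdir / "regions.csv", index=False)
        stage("segmentation", n_frames=n_frames,
              n_regions=sum(len(r) for r in regions_per_frame))

        tracks, events = trk.build_tracks(
            regions_per_frame, weights=config.match_weights,
            gate_distance=config.gate_distance, complete_only=config.complete_only,
        )
        (outdir / "events.json").write_text(json.dumps(events, default=str, indent=2))
        if not tracks:
            raise PipelineError(
                "zero complete tracks after tracking; check gate_distance and "
                "segmentation parameters"
            )
        tracks_df = trk.tracks_to_dataframe(tracks)
        tracks_df.to_csv(outdir / "tracks.csv", index=False)
        for tr in tracks:
            boundaries_by_track[tr.cell_id] = [
                edgemod.polar_resample(r.boundary, r.centroid, config.n_markers,
                                       config.pixel_size, frame=f)
                for f, r in zip(tr.frames, tr.regions)
            ]
        stage("tracking", n_tracks=len(tracks), n_events=len(events))
    else:
        raise PipelineError("config must set input_movie or input_tracks")

    # --- motility features ------------------------------------------------
    feat_rows = []
    for tid, grp in tracks_df.sort_values("frame").groupby("track_id"):
        pos = grp[["centroid_row", "centroid_col"]].to_numpy()
        feats = motmod.motility_features(pos, config.pixel_size, config.frame_interval)
        feat_rows.append({"track_id": tid, **feats.as_dict(), "fit_flag": feats.fit_flag})
    motility_df = pd.DataFrame(feat_rows)
    motility_df.to_csv(outdir / "motility.csv", index=False)
    stage("motility", n_cells=len(motility_df),
          n_flagged=int((motility_df["fit_flag"] != "").sum()))

    # --- edge prints ------------------------------------------------------
    edge_df = None
    if boundaries_by_track:
        rows = []
        for tid, bnds in boundaries_by_track.items():
            ep = edgemod.edge_print(bnds, config.frame_interval,
                                    tau_frames=config.tau_frames, cell_id=tid)
            row = {"track_id": tid}
            row.update({f"p_{i + 1}": v for i, v in enumerate(ep.protrusion)})
            row.update({f"r_{i + 1}": v for i, v in enumerate(ep.retraction)})
            provl, retvl = corr.time_average_edge(ep)
            row["ProVL_um_per_min"], row["RetVL_um_per_min"] = provl, retvl
            rows.append(row)
        edge_df = pd.DataFrame(rows)
        edge_df.to_csv(outdir / "edge_prints.csv", index=False)
        stage("edge_dynamics", n_cells=len(edge_df),
              n_features=2 * (n_frames - config.tau_frames))

    # --- profiling --------------------------------------------------------
    feat_cols = list(sim.MOTILITY_FEATURE_NAMES)
    x = motility_df[feat_cols].to_numpy(dtype=float)
    if config.standardize:
        mu, sd = x.mean(axis=0), x.std(axis=0)
        x = (x - mu) / np.where(sd > 0, sd, 1.0)
    assign = motility_df[["track_id"]].copy()
    model_report: dict = {}
    k_lo, k_hi = config.k_range
    if x.shape[0] > max(k_hi, x.shape[1]):
        sel = prof.select_k(x, k_lo, k_hi, random_state=_substream(config.seed, "gmm"))
        assign["cell_class"] = sel.best_model.predict(x)
        model_report = {
            "k_best": sel.k_best,
            "mdl_by_k": {str(k): v for k, v in sel.mdl_by_k.items()},
            "weights": sel.best_model.weights_.tolist(),
            "means": sel.best_model.means_.tolist(),
            "covariances": sel.best_model.covariances_.tolist(),
        }
        stage("profiling_gmm", k_best=sel.k_best)
    else:
        assign["cell_class"] = 0
        stage("profiling_gmm", skipped="too few cells for the configured k range")

    if edge_df is not None:
        edge_cols = [c for c in edge_df.columns if c.startswith(("p_", "r_"))]
        assign = assign.merge(edge_df[["track_id"]], on="track_id", how="left")
        assign["edge_subclass"] = -1
        for cls, grp in assign.groupby("cell_class"):
            sub = edge_df.set_index("track_id").loc[grp["track_id"], edge_cols].to_numpy()
            k_max_feasible = int(np.floor(config.kmeans_sample_frac * len(sub)))
            if k_max_feasible < 2:
                continue
            lo, hi = config.edge_k_range
            hi = min(hi, k_max_feasible, len(sub) - 1)
            if len(sub) > sub.shape[1] + 1 and hi >= lo:
                sel_e = prof.select_k(sub, lo, hi,
                                      random_state=_substream(config.seed, f"edge_k_{cls}"))
                k_edge = sel_e.k_best
            else:
                k_edge = min(2, k_max_feasible)
            labels, _, _ = prof.two_phase_kmeans(
                sub, k_edge, sample_frac=config.kmeans_sample_frac,
                n_iter=config.kmeans_iter,
                random_state=_substream(config.seed, f"kmeans_{cls}"),
            )
            assign.loc[grp.index, "edge_subclass"] = labels
        stage("profiling_kmeans", n_classes=int(assign["cell_class"].nunique()))
    assign.to_csv(outdir / "assignments.csv", index=False)
    if model_report:
        (outdir / "model.json").write_text(json.dumps(model_report, indent=2))

    # --- correlation ------------------------------------------------------
    if edge_df is not None:
        merged = motility_df.merge(
            edge_df[["track_id", "ProVL_um_per_min", "RetVL_um_per_min"]], on="track_id"
        ).merge(assign[["track_id", "cell_class"]], on="track_id")
        reports = {}
        num_cols = feat_cols + ["ProVL_um_per_min", "RetVL_um_per_min"]
        edge_cols = [c for c in edge_df.columns if c.startswith(("p_", "r_"))]
        fa_table = merged.merge(edge_df[["track_id"] + edge_cols], on="track_id")
        fa_cols = feat_cols + edge_cols
        groups = [(str(c), g) for c, g in merged.groupby("cell_class")]
        groups.append(("pooled", merged))
        for cls, grp in groups:
            if len(grp) < max(4, len(num_cols) + 2):
                reports[cls] = {"skipped": f"only {len(grp)} cells"}
                continue
            rep = corr.spearman_with_p(grp[num_cols], alpha=config.alpha)
            r2 = corr.multiple_correlation(grp[num_cols], response=config.response)
            jk = corr.jackknife_correlation(
                grp, feat_cols, ["ProVL_um_per_min", "RetVL_um_per_min"])
            reports[cls] = {
                "n": rep.n, "r_squared": r2,
                "rho": rep.rho.round(6).to_dict(),
                "significant": rep.significant.to_dict(),
                "jackknife": jk.round(6).to_dict(),
            }
            rep.rho.to_csv(outdir / f"spearman_class{cls}.csv")
            jk.to_csv(outdir / f"jackknife_class{cls}.csv")
            sub = fa_table if cls == "pooled" else fa_table[
                fa_table.cell_class == grp.cell_class.iloc[0]]
            if len(sub) > len(fa_cols) + 1:
                fa = corr.CovarianceFactorAnalysis().fit(sub[fa_cols].to_numpy())
                fa.loading_table(fa_cols, threshold=0.4).to_csv(
                    outdir / f"factor_loadings_class{cls}.csv")
                pd.DataFrame(fa.loadings_corr_, index=fa_cols).to_csv(
                    outdir / f"factor_loadings_full_class{cls}.csv")
                reports[cls]["factors"] = {
                    "n_retained": fa.n_factors_,
                    "variance_explained_pct": fa.variance_explained_.round(3).tolist(),
                    "cumulative_pct": fa.cumulative_variance_.round(3).tolist(),
                }
        (outdir / "correlation.json").write_text(json.dumps(reports, indent=2))
        stage("correlation", n_classes=len(reports) - 1)

    (outdir / "log.json").write_text(json.dumps(log, indent=2))
    return outdir


def make_demo(seed: int = 0, outdir: str | Path = "morphodyn_demo") -> dict:
    """Generate a small fixture movie plus a manifest of output hashes.

    The manifest records sha256 digests of the deterministic stage outputs so
    integration tests can validate a fresh checkout end to end.
    """
    outdir = Path(outdir)
    movie = sim.simulate_cell_movie(sim.SimulationConfig(
        n_cells=4, image_shape=(320, 320), seed=seed))
    paths = sim.write_movie(movie, outdir / "data")
    cfg = RunConfig(
        input_movie=str(paths["movie"]), outdir=str(outdir / "run"),
        k_range=(2, 2), seed=seed,
    )
    run_pipeline(cfg)
    manifest = {}
    for name in ("tracks.csv", "motility.csv", "edge_prints.csv"):
        p = outdir / "run" / name
        manifest[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
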