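# morphodyn

Cell morphodynamics profiling from time-lapse microscopy: who is moving, how,
and what their membranes are doing while they move.

Time-lapse high-content imaging of motile cells (the motivating system is
cultured IC-21 mouse macrophages, imaged every 10 minutes over 2 hours as
12-bit frames with 0.5 µm² pixels) produces heterogeneous populations whose
subtypes differ both in whole-cell kinetics and in membrane (edge) activity.
`morphodyn` implements the full analysis chain for such movies:

1. **Segmentation** — two-phase piecewise-constant ("active contours without
   edges") energy minimisation separates bright cells from the dark
   background; touching cells are split by a marker-controlled watershed on
   the smoothed distance transform.
2. **Tracking** — frame-to-frame minimum-cost matching on position, size and
   intensity, with a three-frame heuristic that distinguishes cell division
   (both daughters persist) from over-segmentation (the extra fragment has no
   future and is merged back). Only cells observed over the entire movie
   enter the analysis.
3. **Motility features** — each centroid track is summarised by the
   persistent random walk (PRW) model. The mean squared displacement

   ⟨d²(t)⟩ = 2S²P·[t − P(1 − e^(−t/P))]

   is fitted by weighted nonlinear least squares for the RMS speed *S* (µm/h)
   and persistence time *P* (h); the feature set is completed by the
   chemotactic index CI = TD/TPL, total path length (TPL), total
   displacement (TD), random motility coefficient RMC = S²P/2, mean path
   length MPL = TPL/(T−1), and persistence length PrL = S·P.
4. **Edge prints** — the package's distinctive feature set. M equiangular
   markers are placed on each cell boundary in polar coordinates about the
   cell's own centroid; between frames each marker's radial displacement is a
   protrusion (outward) or retraction (inward). Per interval,
   p_t = (1/Mτ)·Σ max(Δ_m, 0) and r_t = (1/Mτ)·Σ max(−Δ_m, 0) give
   protrusion/retraction velocities (µm/min); a 12-frame movie yields the
   22-feature edge print (11 + 11).
5. **Subpopulation discovery** — Gaussian mixture models fitted by EM for
   every candidate order K, with the minimum description length
   MDL(K) = −log L + ½·L_p·log(N·n) selecting the number of cell classes;
   edge-print subclasses within each class come from two-phase K-means
   (a 10% subsample seeds the full-data pass).
6. **Correlation** — Spearman rank correlations between motility and
   time-averaged edge features with t-transform p-values, multiple
   correlation R² (speed regressed on everything else), leave-one-out
   jackknife, and covariance-based factor analysis with Kaiser retention and
   varimax rotation.

A synthetic-movie generator (`morphodyn.simulate`) renders deforming,
PRW-moving cells with exact ground truth (masks, tracks, marker radii, edge
prints), closing the testing loop for every stage without any external data.

## Worked example

```python
from morphodyn import simulate as sim
from morphodyn.pipeline import RunConfig, run_pipeline
import pandas as pd

movie = sim.simulate_cell_movie(sim.SimulationConfig(seed=1))   # 8 cells, 12 frames
paths = sim.write_movie(movie, "demo_data")
out = run_pipeline(RunConfig(input_movie=str(paths["movie"]),
                             outdir="demo_run", k_range=(2, 4), seed=1))
print(pd.read_csv(out / "motility.csv").round(3).head(4))
```

which prints (first four tracked cells):

```
 track_id  speed_um_per_h  persistence_h  chemotactic_index  persistence_length_um
        0           9.958          0.718              0.762                  7.149
        1           8.302          0.346              0.668                  2.869
        2           8.032          0.367              0.839                  2.949
        3           8.650          2.686              0.953                 23.233
```

The generator ran all cells at S = 10 µm/h, P = 2 h; single 12-frame tracks
carry limited information, so per-cell estimates scatter around the truth
(speeds 8–10 µm/h here) — exactly the uncertainty a real 2-hour assay has.
`edge_prints.csv` holds the 22 edge features per cell plus their time
averages (ProVL, RetVL):

```
 track_id    p_1    p_2    r_1    r_2  ProVL_um_per_min
        0 0.0991 0.0952 0.0965 0.0969            0.0992
        1 0.0992 0.0983 0.0999 0.0990            0.0981
```

With the default boundary modes (rotating lobes of 2.5/1.5/0.8 µm amplitude)
protrusion and retraction balance at ≈0.1 µm/min, and each measured print
matches the generator's emitted ground truth within 5% RMS.

The same stages are available from the shell:

```bash
morphodyn simulate --outdir data --n-cells 8 --seed 1
morphodyn run-all --movie data/movie.tif --outdir run --k-min 2 --k-max 10 --seed 1
```

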