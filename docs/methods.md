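# Methods

This note documents the models, numerical choices and limitations behind
`morphodyn`, in the order the pipeline runs them.

## Segmentation

Cells are bright, roughly convex objects on a dark, relatively uniform
background. We segment each frame by minimising the two-phase
piecewise-constant (active-contours-without-edges) energy

    E(m, c1, c2) = Σ_fg (I − c1)² + Σ_bg (I − c2)² + µ · Len(m)

over binary labelings `m`, with `Len` the 4-neighbour (anisotropic) contour
length. The image is normalised to unit dynamic range so the length weight
`µ` (default 0.1) is expressed relative to a squared intensity contrast of
one; the regularisation is carried by the length term alone (no area term).

Rather than evolving a level-set function by gradient descent, we minimise
the energy by exact block coordinate descent: checkerboard pixel sweeps
(each parity update is an exact minimisation given the other parity and the
phase means) alternate with closed-form updates of `c1, c2`. This makes the
energy non-increasing at every step by construction, gives a clean stopping
rule (relative energy decrease < `tol`, default 1e-6), and is deterministic.
On a noisy disc fixture it agrees with a gradient-descent level-set solver
of the same energy to Dice ≥ 0.99 (checked in the test suite). A constant
image returns an empty foreground with a warning flag. The brighter phase is
always reported as foreground.

Touching cells are split by watershed on the negated smoothed distance
transform (Gaussian σ = 2 px), seeded at its regional maxima with
prominence below 2 px suppressed (h-maxima). The prominence floor matters:
lobed cell shapes produce shallow secondary distance maxima (< 1–2 px after
smoothing) that must not seed splits, while the saddle between genuinely
touching cells (e.g. discs overlapping at 1.5 radii) is several pixels deep
and still does. The watershed never changes the union of foreground pixels.

Region boundaries are sub-pixel marching-squares contours, lightly smoothed
by a 5-vertex circular moving average: raw marching-squares staircases
overestimate boundary length by ~7% on a circle, while the smoothing's
inward bias is O(R·δθ²), far below a pixel at cell sizes. Regions smaller
than `min_area` = 50 px are discarded as specks. Coordinates are (row, col),
0-based, boundaries oriented counter-clockwise in (x = col, y = row).

## Tracking

Regions of consecutive frames are matched by minimum-cost bipartite
assignment with cost

    w_pos·‖Δcentroid‖/gate + w_size·|ΔA|/max(A) + w_int·|ΔI|/max(I)

with defaults (0.5, 0.25, 0.25) and a centroid gate of 50 px — position
dominates at 10-min sampling; boundary overlap between frames is never
assumed. Candidates whose cost is within 1.5× of a region's assigned match
form the one-to-many structure that the three-frame heuristic classifies: a
one-to-two link is a division iff both putative daughters have their own
matches one frame later, otherwise an over-segmentation whose fragments are
merged back (pooled area/centroid/intensity, boundary re-traced from the
union of pixels); two-to-one links are handled symmetrically. After any
merge the affected frame pair is re-matched. First-frame fragments are
merged only when both fragments' tracks begin at that frame; fragments with
longer distinct histories are kept separate and logged rather than guessed
at. Ambiguities at the final frame
(no third frame available) default conservatively to the nearest match and
are logged. A division closes the parent track and opens two child tracks,
so the complete-tracks filter (the default for all downstream feature
extraction) keeps exactly the cells observed over every frame.

## Motility features

The geometric centroid track, converted to µm and hours, is summarised by
eight features. The MSD over all lags with overlapping-interval averaging is
fitted to the 2-D persistent-random-walk form

    ⟨d²(t)⟩ = 2 S² P [t − P (1 − e^(−t/P))].

Two numerical points deserve record:

* **Weighting.** The sampling variance of an MSD estimate scales as
  msd²/n_pairs, so residuals are relative (per-lag msd scale) with
  √n_pairs weight. Absolute residuals would hand the fit to the long lags
  — which are both statistically useless (few pairs, strong correlation)
  and large in µm² — and push single-track fits onto the degenerate
  diffusive ridge S → ∞, P → 0 at constant S²P; we observed exactly this
  failure mode before adopting relative weighting.
* **Optimisation.** At fixed P the model is linear in S², so S is profiled
  out in closed form and the remaining 1-D problem in P is solved on a dense
  logarithmic grid (serving as multi-start across sub-frame to super-window
  time scales) refined by bounded Brent minimisation. Both parameters are
  positive by construction; a noiseless curve is recovered to better than
  four significant digits. Fits with P beyond 10× the observation window are
  flagged `ballistic` (P unidentified, S still meaningful); a degenerate
  profile falls back to first-lag estimates with a `fallback` flag — never a
  silent failure.

The remaining features are defined as CI = TD/TPL (∈ [0,1], 0 for a
stationary track), PrL = S·P, RMC = S²P/2 (the 2-D long-time diffusion
coefficient), MPL = TPL/(T−1). These definitions are declared package
conventions: PrL = S·P reproduces the reference per-class persistence
lengths exactly at 2-decimal rounding, whereas no simple function of
(S, P, TPL) reproduces the reference RMC and MPL columns, whose originating
definitions are not restated in the source literature.

**Information limit of single-track recovery.** A 100-frame track at 10-min
sampling with P = 2 h spans ~8 velocity correlation times. For an OU/AR(1)
velocity process the Fisher information bounds the variance of any estimate
of the stationary velocity variance by ≈ 2(1+ρ²)/(N(1−ρ²)) relative
(ρ = e^(−Δt/P) ≈ 0.92, N = 2×99 component-steps), i.e. std(Ŝ)/S ≈ 17%,
median |error| ≈ 11–12%. Our fit achieves a ~13–14% median at 10-min
sampling — the best interval; coarser sampling loses velocity resolution and
finer sampling shortens the window, both worse — and an approximate
exact-discretisation MLE achieves 11.7%, so no estimator reaches a 10%
median under these conditions. On 500-frame tracks the same fit reaches a
5.7% median, confirming the estimator, not the implementation, is at its
information limit. The acceptance suite states the 100-frame bound anyway
and that test fails honestly.

## Edge prints

Boundaries are aligned on their own centroids (translation is removed;
rotation is deliberately **not** compensated) and resampled onto M
equiangular rays; the radius along each ray is the outermost boundary
crossing, which preserves protruding tips of non-star shapes
deterministically. M defaults to 360 (1° resolution, finer than any feature
at 0.707 µm pixels); per-marker normalisation makes the print insensitive to
M (doubling M changes features by < 2% on smooth boundaries). Displacements
over the sampling interval τ (default one frame, 10 min) are split by sign:

    p_t = (1/Mτ) Σ_m max(Δ_m, 0),   r_t = (1/Mτ) Σ_m max(−Δ_m, 0)

in µm/min; the marker-sum variant (total boundary displacement) is available
via `normalize=False`. Both are non-negative by construction, zero under
rigid translation, and a 12-frame track gives the 22-feature print. Edge
prints measure membrane activity, not migration: vigorous ruffling without
translocation scores high.

## Synthetic data

The generator defines the package's study conditions: 12 frames at 10-min
intervals, 12-bit intensities, 0.707 µm pixels; 8 cells of base radius 15 µm
with boundary r(θ,t) = R + Σ aⱼ sin(fⱼθ + φⱼ + ωⱼt), modes
(f, a, ω) = (2, 2.5 µm, 0.9), (3, 1.5 µm, 1.7), (5, 0.8 µm, 2.6 rad/frame),
random phases per cell; constant foreground 3000 on background 200 with
additive Gaussian noise (sd 100); centroids move by an exactly discretised
persistent random walk (integrated OU velocity sampled jointly with position
at the exact conditional covariance), so the ensemble MSD matches the
closed form at every lag with no time-step bias. Cells are placed so the
bounding discs of their whole tracks never overlap; an optional division
event replaces one cell by two separating daughters to exercise the
tracking heuristic.

Ground truth is emitted in the measurement's own convention: per-frame
marker radii about the shape's *area* centroid (computed from the polar
form) on the same equiangular grid, and edge prints derived from those
radii. What the generator does **not** emulate — photophysics, shot noise,
uneven illumination, cell–cell contact, rotation, shape changes that are
not radial about the centroid — bounds what passing tests demonstrate:
accuracy of the numerics and the pipeline plumbing, not robustness to every
property of real micrographs.

Default mixture means for the feature-table generator are the mean motility
profiles of the four reference macrophage subpopulations
(slow/erratic, slow/persistent, fast/persistent, fast/erratic), with a
small isotropic covariance (sd 0.5 in raw feature units), so
model-order-selection tests run under realistic class geometry.

## Profiling

EM for full-covariance Gaussian mixtures is implemented in-package (the
per-iteration log-likelihood trajectory is exposed and asserted monotone in
tests; sklearn's EM is the independent likelihood oracle). Initialisation is
K-means; covariances carry a ridge of 1e-6 × mean feature variance to stay
positive definite through degenerate clusters. Restarts (≤ 5) run until the
first convergence; among executed converged runs the best log-likelihood
wins. Model order is chosen by

    MDL(K) = −log L + ½ L_p log(N·n),   L_p = K(1 + n + n(n+1)/2) − 1,

minimised over the candidate range (the `log(N)`-only penalty variant is one
config switch away). Features are z-scored before clustering — they span
three orders of magnitude — and non-normal features are flagged by the
diagnostics (probability-plot coordinates with probit-scaled ordinates and a
first/third-quartile reference line; chi-square GOF with equal-probability
bins under the moment-fitted normal, df = n_bins − 3) but never dropped
automatically.

Two-phase K-means: phase 1 clusters a uniform random 10% subsample
(≤ 1000 iterations); its centroids seed phase 2 on all rows, whose objective
can therefore only improve on the phase-1 configuration. The number of edge
subclasses per cell class defaults to MDL-selected order on the class's edge
prints, with a fixed-K override.

## Correlation

Spearman ρ is computed as Pearson correlation of average ranks; two-sided
p-values use t = ρ√((N−2)/(1−ρ²)) on N−2 d.f. (within 0.02 of the exact
permutation distribution at N = 8, checked exhaustively), flagged at raw
α = 0.05 as the headline convention with Benjamini–Hochberg flags emitted
alongside. Multiple correlation is the R² of an OLS fit of speed on all
other features. The jackknife reports mean ± sd (ddof = 1) of the N
delete-one correlation estimates per (motility, edge) pair, Spearman by
default for consistency with the main analysis.

Factor analysis is principal-axis extraction from the covariance matrix
(loadings = eigenvectors × √eigenvalues), Kaiser retention applied to the
eigenvalues of the correlation-scaled matrix (≥ 1), varimax rotation of the
retained loadings (rotation and extraction both configurable, including
none). Covariance-scale and correlation-scale loading matrices are both
kept; the report view suppresses |loading| < 0.4 on the standardised scale.
Per-class analyses are primary; a pooled analysis over all classes is also
emitted since reference reports present a single loading table.

## Pipeline

All stochastic stages draw seeds from one root seed through named SHA-256
substreams, so partial reruns reproduce full runs bit-identically; CSV is
the inter-stage contract (units embedded in headers), JSON carries models
and reports, and each stage logs input/output counts. Statistical stages
whose per-class sample size is insufficient (e.g. factor analysis with
fewer cells than features) are skipped and logged rather than failed; zero
complete tracks abort the run with an explanatory error.

## Problem sizes used in the test suite

Suites run on one CPU in ≲ 3 minutes total: the shared synthetic movie is
8 cells × 12 frames at 448×448 px; ensemble MSD checks use 2000 tracks;
single-track recovery studies use 500 (12- and 100-frame) or 150 (500-frame)
tracks; MDL order recovery uses 20 seeds × 2000 samples over K = 2..10; the
permutation oracle enumerates all 8! rank permutations.

## Known limitations

* Radial (not boundary-normal) marker displacement; fast tangential motion
  of oblique membrane segments is under-measured.
* No rotation compensation — a rotating rigid cell shows spurious
  protrusion/retraction if its shape is anisotropic.
* Gap closing across more than one missing frame is out of scope; a cell
  lost for one frame starts a new (incomplete) track.
* The discrete length penalty is anisotropic (4-neighbour); contour-length
  estimates are corrected by boundary smoothing rather than by a
  multi-direction (Cahn–Hilliard/Crofton) penalty.
* Single-track PRW parameter estimates on short tracks are information-
  limited (see above); per-class averages, not per-cell values, are the
  meaningful readout at 12 frames.
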