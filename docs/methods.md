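# Methods

## Model overview

The package implements a linear successor-feature model over boundary
vector cell (BVC) basis features. The components are:

1. **Environment** (`geometry`): a closed polygonal perimeter plus internal
   barrier segments, all in meters. Boundary distance queries are exact
   ray–segment intersections; barriers are opaque (a BVC sees the nearest
   boundary along each direction). The environment also owns the rate-map
   binning (2 cm bins by default).
2. **BVC population** (`bvc`): a polar grid of preferred distances ×
   directions with Gaussian tuning, radial width growing linearly with
   preferred distance.
3. **Foraging** (`motion`): a rodent-like random walk at 50 Hz.
4. **Learning** (`sr`): online TD learning of the successor matrix M̃ over
   BVC features, one update per 20 ms sample.
5. **Readout** (`cells`): place maps as thresholded successor features,
   grid maps as thresholded eigenvectors of M̃.
6. **Analysis** (`gridmetrics`, `fields`): autocorrelogram-based grid
   metrics and place-field event analyses.
7. **Baseline** (`baseline`): the standard discrete-state (grid-world) SR
   for head-to-head comparisons.
8. **Protocols** (`experiments`): six seeded end-to-end pipelines.

## Parameters and defaults

| parameter | default | units | role |
|---|---|---|---|
| preferred distances | 10 values, geometric in [0.05, 0.8] | m | BVC radial layout |
| preferred directions | 16, uniform | rad | BVC angular layout |
| β, ξ | 12, 0.05 | –, m | σ_rad(d) = d/β + ξ |
| σ_ang | 0.2 | rad | angular tuning width |
| n_dirs | 360 | – | directions in the rate integral |
| dt | 0.02 | s | 50 Hz sampling |
| mean speed | 0.13 | m/s | Rayleigh speed distribution |
| turn σ | 5.9 | rad/s | SD of angular velocity; heading increment SD = 5.9·dt ≈ 6.8°/step |
| wall margin / turn | 0.03 m / U(π/4, π/2) | | avoidance clearance and turn |
| γ | 0.99 | per step | discount; ≈2 s horizon ≈ 0.26 m of travel |
| α_M̃ | 0.01 | – | TD learning rate (unit-peak features) |
| duration | 2400 | s | 40 simulated minutes per learning phase |
| rate-map bin | 0.02 | m | analysis grid |
| baseline state bin | 0.05 | m | ≈400 states in a 1 m arena |

All are configurable (`make_population`, `MotionParams`,
`ExperimentConfig`); every experiment summary records the values used.
The defaults are conventions: the BVC tuning constants follow the
established BVC-model literature, and the arena presets (1 m square,
{1×1, 1×2, 2×1, 2×2} m stretch family, 1 m circle as a 64-gon, trapezoid
with 0.9 m/0.2 m parallel ends and 1.9 m length, 2 m hairpin maze with 7
internal walls) follow the classic experimental designs for each
manipulation. γ and α_M̃ trade off field size against convergence speed;
with unit-peak features, 40 minutes of updates at α = 0.01 reaches a stable
M̃ whose place fields are compact and unimodal for most cells.

## Feature normalisation and manipulated environments

Tuning kernels fix rates only up to a proportionality constant, so after
construction each BVC is rescaled to unit peak over the **training**
environment's bins. When the environment is manipulated (stretched, barrier
inserted or removed) the training gains are reused: geometric change then
appears as genuine change in f(s), never as renormalisation. Features along
a trajectory are read from the precomputed bin grid (containing-bin lookup),
bounding the error by the 2 cm bin size while removing ~40 million ray
casts per run.

## Motion model

Speed is redrawn each step from a Rayleigh distribution with the configured
mean; heading integrates white Gaussian angular velocity (increment
N(0, (turn_σ·dt)²)). If the look-ahead clearance along the new heading is
inside the wall margin, the agent turns toward the more open side by a
uniform draw from the wall-turn range and halves its speed; steps that would
exit the arena or cross a barrier are rejected and redrawn (the agent can
always pause in place, so confinement cannot deadlock). Speed is white
rather than autocorrelated — a simplification that leaves occupancy
near-uniform in open arenas but underrepresents run-and-pause structure.

## Readout conventions

* Place maps: raw activation is the M̃-row-weighted BVC sum per bin;
  threshold at 80% of the map's maximum; suprathreshold remainder
  peak-normalised to 1.
* Eigenmodes: M̃ is decomposed directly (it is non-symmetric; complex pairs
  are reduced to their real parts) and modes sorted by descending real
  eigenvalue. Symmetrising before decomposition is available but not the
  default. Eigenvector signs are fixed by choosing the sign whose
  thresholded map has the larger spatial mean; degenerate (all-zero) maps
  are retained but flagged and excluded from population statistics.
* The initial successor matrix is the identity: ψ̃ includes the t = 0 term
  of the discounted sum, so M̃ = I is the correct zero-knowledge prior.
* Manipulation protocols learn continually: the post-manipulation phase
  starts from the pre-manipulation M̃.

## Analysis conventions

* **SAC**: masked Pearson autocorrelation over all integer lags; lags with
  fewer than 20 overlapping valid bins are missing. SAC peaks are local
  maxima (correlation > 0.1, ≥3 bins apart) refined to sub-bin precision by
  per-axis parabolic interpolation — without refinement, eccentricity
  estimates of near-circular peak rings are badly inflated by bin
  quantisation.
* **Gridness**: expanding-annulus score — inner radius from the central
  peak's extent, outer radius swept; per annulus the SAC is correlated with
  itself rotated by 30/60/90/120/150°, score = min(r60, r120) −
  max(r30, r90, r150), best annulus kept.
* **Ellipticity**: eccentricity √(1 − (b/a)²) of the least-squares centered
  conic through the six SAC peaks nearest the center; undefined with fewer
  than six peaks.
* **CV**: fields are connected components above 50% of the map peak
  (configurable); CV = sample SD (n−1) / mean of per-field peak rates;
  undefined with fewer than two fields.
* **Grid-cell criterion**: pooled null distribution built by permuting
  eigenvector weights across BVC identities (destroying spatial coherence,
  preserving the weight distribution), 200 null maps cycling over modes;
  threshold = 95th percentile of null gridness.
* **Orientation KL**: grid-axis orientation is the angle to the nearest
  off-center SAC peak mod 60°; the divergence from uniform uses a 20-bin
  histogram over [0°, 60°). The headline statistic pools **all** eigenmode
  orientations: with only the dozen-odd classified grid cells a 20-bin
  histogram has a small-sample floor of ln(20/n) nats, so a near-uniform
  value of a few hundredths is measurable only at population size.
* **Equal-area halves**: the square splits at its vertical midline; the
  trapezoid's split line is found by root-finding on the clipped polygon
  area (half-masks match to <1% of bins).
* **Barrier duplication**: a cell duplicates if its field count increases
  at insertion *and* fields lie strictly on both sides of the barrier's
  supporting line (centroid side, restricted to the barrier's bounding
  strip). A duplicate is "lost" if the field count returns to its
  pre-insertion value after the relearning phase.
* **Hairpin arms**: channels between consecutive internal walls; maps are
  restricted to congruent center-cropped arm frames with odd arms flipped
  vertically (alternating traversal direction) before correlating.

## Baseline variants

`tabular_sr` computes M = (I − γP)⁻¹ for the uniform random walk on the
accessible 5 cm bins (transitions blocked by walls and barriers) — the
spec-standard closed form, used for the oracle tests and the
barrier-insertion contrast (its maps derive from M alone, so barrier
insertion without relearning changes nothing, exactly). `tabular_sr_td`
TD-learns the same representation from a 50 Hz trajectory with one-hot
state features — the parity variant whose eigenvectors carry the same kind
of sampling noise as the feature model's. The open-field experiment reports
both: the closed form's exactly symmetric grid gives artificially clean
plaid eigenmodes (lower ellipticity, lower CV), the learned variant breaks
the symmetry (higher ellipticity and CV). The model contrasts in the
acceptance suite use the closed-form default.

## What the simulations do and do not show

All data are self-generated: the trajectory generator emulates foraging
statistics (speed distribution, heading diffusion, wall avoidance), not any
particular animal's path, and BVC tuning is noiseless — there is no spiking
variability, theta rhythmicity, or measurement noise. Passing tests
therefore demonstrate properties of the model under idealized sampling, not
fits to recordings.

The qualitative phenomena are robust here: unimodal boundary-conforming
place fields; immediate affine deformation under stretches with preserved
relative field sizes; immediate barrier-induced field duplication with no
SR change, partial loss of duplicates after relearning, zero immediate
response in the tabular baseline; higher half-arena SAC similarity in a
square than a trapezoid; orientation distributions more polarized in a
square than a circle; checkerboard arm correlations in the hairpin maze.

The *magnitudes* of several population statistics are sensitive to
quantities the underlying study design leaves open — γ, α_M̃, the BVC
layout, and arena dimensions all shape grid scale, field counts and
peak-rate variability. In particular the mean per-field peak-rate CV, the
narrow-half trapezoid gridness, and the exact number of eigenmodes passing
the shuffled criterion (and hence which model's classified "grid cells"
score higher) vary substantially with those choices; the experiment
summaries expose the full per-mode tables so any alternative setting can be
re-measured directly.

## Numerical notes

* Ray casting is vectorised over segments; positions × directions are
  chunked to bound memory. Degenerate (parallel) ray–segment pairs are
  excluded by a 1e-14 determinant guard.
* The TD loop is O(n²) per step (two mat-vecs and an outer product);
  120 000 updates of a 160-cell model take seconds.
* Eigen decomposition uses LAPACK via `numpy.linalg.eig`; ties in the
  degenerate identity-matrix case keep index order.
* SACs are computed with FFT cross-correlations of the map, its square and
  its mask; rotation uses bilinear interpolation with a 0.99 validity
  cutoff on the rotated mask.
* The ring-oracle convergence test uses a Robbins–Monro schedule
  α_t = α₀/(1 + t/τ); constant-α TD orbits a noise ball and cannot reach
  the 2%-per-entry target.
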