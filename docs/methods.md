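# Methods

## Scope and model

`subdiff` implements the single-particle-tracking (SPT) analysis used to
compare the anomalous diffusion of chromosomal loci and cytoplasmic
particles in bacteria, together with simulators that generate trajectories
with the statistical structure the analysis assumes.  The central model is
the 2-D anomalous-diffusion law for the ensemble-averaged mean-squared
displacement,

    MSD(τ) = 4 D_app τ^α ,

with the apparent diffusion coefficient D_app in μm² s^−α and the
dimensionless exponent α (α = 1 normal diffusion, α < 1 subdiffusion).
The package estimates (α, D_app) by unweighted ordinary least squares of
log₁₀ MSD on log₁₀ τ, with 95% confidence intervals from the regression
t-distribution — deliberately the same procedure as a MATLAB
`fit`/`confint` pipeline, so results are comparable with the experimental
literature this emulates.

## Synthetic-data generators (`subdiff.simulate`)

The raw experimental movies these methods were developed for are not
publicly deposited, so the generators are first-class, tested code; every
downstream stage is validated against their known ground truth.

**Defaults are the study conditions.**  Frame timing is 5 frames/s for
100 s (`dt = 0.2 s`, `n_frames = 500`); ensembles default to 2000 tracks,
matching the thousands-of-tracks scale of the experiments; `alpha` and
`d_app` default to the uncompressed cytoplasmic-particle values
(0.75, 0.0092 μm² s^−α).  The printed experimental exponents span
α ≈ 0.27–0.75 with D_app ≈ 0.0016–0.0092 μm² s^−α; where a recovery test
needs a D_app the source never printed, 0.004 μm² s^−α (mid-range) is
used.  Localization noise defaults to 0 because the acquisitions it
emulates report no localization precision; it is exposed as an option, as
is a rectangular reflecting boundary approximating cell confinement.

**Fractional Brownian motion.**  Subdiffusive tracks are fBm with Hurst
exponent H = α/2, built from fractional Gaussian noise with *exact*
covariance via circulant embedding (Davies–Harte, O(n log n)); if an
embedding were indefinite the sampler falls back to the exact sequential
Durbin–Levinson construction.  Per axis, increments are scaled by
√(2 D_app) so the 2-D ensemble MSD is exactly 4 D_app τ^α.

**Laplace steps by superstatistics.**  Non-Gaussian step distributions
are generated by giving each track its own diffusivity drawn from an
exponential distribution of mean D_app (gamma mixing with coefficient of
variation `cv`; `cv=1` is exponential).  Exponential variance mixing of
Gaussians yields exactly Laplace-distributed pooled 1-D steps (excess
kurtosis 3) while the ensemble MSD stays 4 D_app τ.  This is the simplest
mechanism producing the observed marginals; no mechanistic claim is
attached to it.

**Rouse chains.**  `sim_rouse` simulates an overdamped free-end
bead-spring chain in 2-D, parametrized by the free-bead diffusivity
`d_free` (per-axis MSD of an unconnected bead: 2 d_free t^β) and spring
rate `spring_k` (friction 1).

* β = 1 (classic Rouse): Euler–Maruyama with white thermal noise from an
  equilibrium initial configuration; an explicit-stability check rejects
  4·k·dt ≥ 1.  The centre of mass is Brownian (α = 1) and the middle bead
  shows α = 1/2 between the fastest-mode time 1/(4k) and the chain
  relaxation time ≈ N²/(π²k).
* β < 1 (fractional-Langevin chain): the chain in a viscoelastic medium
  obeys a generalized Langevin equation with power-law memory friction and
  matching (fluctuation–dissipation) fractional noise.  We simulate it
  *exactly* in normal modes: each Rouse mode p is an independent stationary
  Gaussian process with variance kT/λ_p and autocorrelation
  E_β(−λ_p t^β) (Mittag-Leffler), sampled by the same circulant-embedding
  machinery; the centre-of-mass mode is fBm.  This realization reproduces
  the half-exponent prediction α_bead = β/2 at intermediate lags.

  A design note on why the naive alternative is wrong: driving a
  white-friction Rouse chain with *external* fGn (no memory friction)
  gives relaxed-mode variances ∝ λ^−β instead of equipartition's λ^−1,
  and hence a middle-bead exponent β − 1/2, not β/2 — at β = 0.8 that is
  0.3, not 0.4.  Only at β = 1 do the two constructions coincide, which
  is why the Euler–Maruyama path is restricted to white noise.

  The Mittag-Leffler evaluator uses the power series below x = 23^β
  (keeping the peak series term under ~10¹⁰ so float64 cancellation is
  benign) and the optimally truncated asymptotic series above; it is
  verified against E₁(−x) = e^−x and E₁/₂(−x) = erfcx(x) to ~10⁻⁵
  relative accuracy, far below what the covariance sampling can resolve.

**Movie rendering.**  Emitters are drawn as integrated 2-D Gaussians
(pixel value = photon budget × erf-difference mass in the pixel), a
uniform background is added, and Poisson shot noise is applied.  Integer
pixel coordinates are pixel centres; physical position x maps to pixel
x/pixel_size.  Ground-truth per-frame positions are stored on the Movie
for auditing.  Exposure blur is not modelled (acquisition exposure is not
quantified in the source experiments); emitters outside the frame are
clipped with a warning but retained in the ground truth.

## Detection and linking (`subdiff.track`)

The original experiments used an unpublished tracking script; this module
is a documented, tested equivalent, not a reimplementation of it.
Detection: difference-of-Gaussians bandpass (σ_low, σ_high), local maxima
above a threshold (percentile of the bandpassed image by default, 99.5th;
absolute counts optionally), subpixel refinement by intensity-weighted
centroid with one re-centering pass in a window of radius σ_high
(negative bandpass values clipped).  Measured noise-free localization
bias is < 0.02 px; at SNR ≈ 10 the localization error is ≲ 0.1 px.
Linking: greedy mutual-nearest-neighbour assignment between consecutive
frames within `max_disp` (default 5 px), deterministic tie-break by lower
detection index, optional gap bridging over `memory` frames (default 0),
and a `min_length` filter (default 20).  No drift correction is applied
(cells are immobilized in the geometry this emulates).  The detection
threshold should be matched to the spot density: with n spots in N pixels
a percentile threshold above 100·(1 − n/N) starts to drop real spots (the
round-trip test uses the 99.0th percentile at 0.005 spots/px²).

## MSD estimation and fitting (`subdiff.msd`)

`compute_ensemble_msd` uses time-and-ensemble averaging over all start
times (maximizing pair counts, standard SPT practice), requires a uniform
frame interval, and records the pair count per lag.  It is tested for
exact equality against a brute-force all-pairs double loop.

`PowerLawMSD` fits all lags in the window [0.2 s, 10 s] by default — one
frame interval up to the 10 s cutoff that avoids ballistic contamination
at long lags — unweighted, as in the published procedure.  D_app is
extracted with the 2-D factor 4 throughout.  A two-segment variant fits
independently below and above an explicit break lag (break included in
the early window); no automatic changepoint detection is attempted.

**Calibration and the scope of the confidence intervals.**  Over 20
seeded replicates of 2000 fBm tracks × 500 frames, the mean fitted α is
within 0.005 of the generator value for α ∈ {0.3, 0.5, 0.75, 1.0} (the
test asserts < 0.02), and single-run recoveries are within ±0.02 on α and
±5% on D_app.  The *confidence intervals*, however, inherit a known
approximation: MSD points at different lags share underlying
displacements, so residual-based regression CIs are strongly
anticonservative for time-averaged ensemble curves — in our measurements
at this scale the nominal 95% interval covers the generator exponent in
only ~20% of replicates, and a z-test built on such CIs rejects a true
null far above its level.  This is a property of the published fitting
procedure itself, retained deliberately for comparability; the test suite
therefore verifies the CI construction where its assumptions hold
(independent lag noise → ~95% coverage; honest standard errors → null
rejection ≈ level).  Users comparing conditions should read the z-test
against CIs of this kind as a *procedure-level* criterion, not a
calibrated error rate — the same caveat applies to the experimental
significance statements the procedure reproduces.

## Step distributions (`subdiff.stepdist`)

1-D displacements at a fixed lag δ (default 1 s, i.e. 5 frames — long
lags are excluded because membrane confinement truncates them) are pooled
over all tracks and start times along a fixed camera axis (x by
convention; cells are randomly oriented, y is available for symmetry
checks).  Rescaling divides by the sample standard deviation σ_δ
(idempotent by construction).  Fits are maximum likelihood — Laplace:
location = median, scale = mean absolute deviation about the median;
Gaussian: mean and s.d. — and model preference is by log-likelihood,
whose ordering equals AIC's since both families have two parameters.  MLE
was chosen over least squares on the log-histogram (the alternative the
source figures leave ambiguous) because it is binning-free and its
estimators are closed-form.

## Wall mechanics (`subdiff.mechanics`)

The single-wall truncated drag correction D∥/D₀ = 1 − 9a/(16z) is used
exactly as written, valid for z > 9a/16; no two-wall superposition and no
full series solution are implemented.  The wall distance convention is
z = h/2 (particle centred between the plates), and the default
uncompressed height h0 = 1.0 μm is a typical rod-shaped-cell width — both
are parameters because the source analysis states neither.  Constant
volume links footprint-area increase f to height decrease 1 − 1/(1+f)
(72% area increase ↔ 42% height decrease).  Because the reference state
behind any single "percent slowdown" number is ambiguous,
`compression_slowdown` reports both conventions (compressed vs unconfined:
9a/16z; compressed vs uncompressed-confined: 1 − ratio(z)/ratio(z₀)) and
labels them.

## Problem sizes used in tests and the acceptance script

Parameter-recovery runs use the full experimental scale (2000 tracks ×
500 frames).  Rouse ensembles use 16–48 chains of 64 beads, 1500–4000
steps, with fit windows chosen a priori to sit well inside the scaling
window (lower edge ≥ 5× the fastest-mode relaxation time, upper edge ≪
the chain relaxation time).  The tracking round trip uses 144 emitters on
a 165×165 px field (0.005 spots/px²) for 200 frames at SNR ≈ 10.  Step
analyses pool 10⁵ displacements from 10⁴ tracks; many short tracks rather
than few long ones, because the kurtosis estimator concentrates with the
number of independent per-track diffusivities.

## Known limitations

* The generators emulate the *statistical* structure of the data (power-law
  MSD, Laplace steps, confinement, shot noise) but not cell-shaped
  boundaries, photobleaching, polydisperse spot brightness, exposure blur,
  or active (ATP-dependent) noise; passing tests demonstrate correctness
  of the pipeline, not biological fidelity of any particular dataset.
* Linking is greedy mutual-nearest-neighbour; no multi-hypothesis or
  Kalman linking, so identity switches appear at high density or large
  per-frame displacements.
* Regression CIs on time-averaged ensemble MSDs are anticonservative (see
  above); per-track exponent distributions are out of scope (only the
  ensemble estimator is provided).
* The fractional-Langevin chain is sampled at equilibrium; transient
  (aging) behaviour is not modelled.
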