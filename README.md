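# subdiff

Single-particle-tracking (SPT) analysis of anomalous diffusion in
bacteria: did a perturbation change how far tracers move, or how that
distance *grows with time*?

Chromosomal loci and cytoplasmic particles in bacteria both subdiffuse:
their ensemble-averaged mean-squared displacement follows

    MSD(τ) = 4 D_app τ^α ,        α < 1,

where D_app (μm² s^−α) sets the mobility scale and the exponent α encodes
the character of the motion (α = 1 viscous fluid; α = 1/2 a Rouse-polymer
segment; a segment of a polymer in a viscoelastic medium is predicted to
show *half* the exponent of a free tracer in the same medium,
α_locus = α_particle/2).  Distinguishing a change in D_app from a change
in α — e.g. under mechanical compression of the cell — is the entire
game, and it requires a pipeline whose estimator biases are known.
`subdiff` provides that pipeline for experimentalists and modellers:

* **simulate** — trajectory generators with known ground truth: fractional
  Brownian motion with exact covariance (circulant embedding), classic and
  fractional-Langevin Rouse chains (exact normal-mode sampling via
  Mittag-Leffler autocorrelations), heterogeneous-diffusivity walks with
  exactly Laplace-distributed steps, and synthetic fluorescence movies
  with Poisson shot noise and stored ground truth;
* **track** — difference-of-Gaussians spot detection with subpixel
  centroid refinement, and mutual-nearest-neighbour linking;
* **msd** — time-and-ensemble-averaged MSD and log-log power-law fits
  with 95% confidence intervals (`PowerLawMSD`, a scikit-learn estimator),
  including restricted-lag and two-segment fits;
* **stepdist** — pooled 1-D displacement distributions at fixed lag,
  σ_δ-rescaling, Laplace-vs-Gaussian maximum-likelihood comparison;
* **mechanics** — the single-wall hindered-diffusion bound
  D∥/D₀ = 1 − 9a/(16z) and constant-volume compression geometry;
* **compare** — z-tests for exponent differences and for the
  half-exponent (viscoelastic Rouse) prediction.

## Worked example

Simulate the two cytoplasmic-particle conditions (uncompressed:
α = 0.75, D_app = 0.0092; compressed: α = 0.72, D_app = 0.0016, both in
μm² s^−α) at the experimental scale — 2000 tracks, 5 frames/s for 100 s —
then run the full analysis:

```python
from subdiff import (SimConfig, sim_tracks, sim_laplace_walk,
                     compute_ensemble_msd, fit_power_law, diff_exponents,
                     extract_steps, rescale, compare_models,
                     compression_slowdown)

fits = []
for alpha, d_app, seed in [(0.75, 0.0092, 1), (0.72, 0.0016, 2)]:
    cfg = SimConfig(model="fbm", alpha=alpha, d_app=d_app, seed=seed)
    curve = compute_ensemble_msd(sim_tracks(cfg), max_lag=10.0)
    fit = fit_power_law(curve, (0.2, 10.0))
    fits.append(fit)
    print(f"alpha = {fit.alpha:.3f} +/- {fit.alpha_ci:.3f}, "
          f"D_app = {fit.d_app:.4f} um^2 s^-alpha")

res = diff_exponents(*fits)
print(f"z = {res.z_stat:.2f}, significant at 95%: {res.significant}")

steps = extract_steps(sim_laplace_walk(SimConfig(
    model="laplace_walk", d_app=0.005, n_tracks=10_000, n_frames=11,
    dt=0.2, seed=3)), delta=0.2)
rep = compare_models(rescale(steps))
print(f"excess kurtosis = {rep.excess_kurtosis:.2f}, "
      f"preferred: {rep.preference}")

r = compression_slowdown(a=0.2, h0=1.0, area_increase=0.72)
print(f"height decrease = {r.height_decrease:.0%}, "
      f"wall-drag decrease vs unconfined = {r.decrease_vs_unconfined:.0%}")
```

Output:

```
alpha = 0.751 +/- 0.000, D_app = 0.0092 um^2 s^-alpha
alpha = 0.721 +/- 0.000, D_app = 0.0016 um^2 s^-alpha
z = 139.05, significant at 95%: True
excess kurtosis = 2.94, preferred: laplace
height decrease = 42%, wall-drag decrease vs unconfined = 39%
```

Reading it: both simulated conditions are recovered to three decimals in
α and to a fraction of a percent in D_app — a ~6× mobility drop with a
nearly unchanged exponent, and the z-test flags even that small exponent
difference because ensemble CIs at this scale are tiny (see
`docs/methods.md` for why such CIs are anticonservative).  The pooled
steps from the heterogeneous-diffusivity walk show excess kurtosis ≈ 3,
the Laplace signature.  The wall-friction bound says a 72% footprint-area
increase (42% height decrease at constant volume) slows even a 200 nm
tracer by only ~39% — far short of an order of magnitude, so wall drag
alone cannot explain mobility drops of that size.

A command-line interface mirrors the library
(`subdiff simulate|track|msd|fit|stepdist|hindrance|compare`, see
`subdiff --help`).

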