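"""Synthetic trajectory and movie generators with known ground truth.

Every statistical structure the downstream analysis assumes can be produced
here with controlled parameters:

* fractional Brownian motion (fBm) tracks whose ensemble MSD follows
  ``MSD = 4 * d_app * t**alpha`` exactly, built from fractional Gaussian
  noise (fGn) sampled by circulant embedding with the exact covariance;
* bead-spring (Rouse) polymer chains, either classic (white thermal noise,
  Euler–Maruyama) or fractional-Langevin (power-law memory, simulated
  exactly in normal modes via Mittag-Leffler autocorrelations), whose
  middle-bead MSD exponent is half the free-tracer exponent;
* heterogeneous-diffusivity ("Laplace walk") ensembles whose pooled 1-D
  displacements are exactly Laplace distributed while the ensemble MSD
  remains that of ordinary diffusion;
* synthetic fluorescence movies rendering emitters as integrated 2-D
  Gaussians with Poisson shot noise, with ground-truth positions retained.

All generators are deterministic under a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .trackset import Movie, TrackSet, _positions_to_trackset

__all__ = [
    "SimConfig",
    "gen_fgn",
    "sim_tracks",
    "sim_laplace_walk",
    "sim_rouse",
    "render_movie",
    "mittag_leffler_neg",
]


# ----------------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------------

_MODELS = ("brownian", "fbm", "rouse", "fle_rouse", "laplace_walk")


@dataclass
class SimConfig:
    """Parameters of a synthetic-track ensemble.

    Defaults mirror the acquisition they emulate: 5 frames/s for 100 s
    (``dt=0.2``, ``n_frames=500``) and an experimental-scale ensemble of
    2000 tracks.  ``alpha`` and ``d_app`` default to the uncompressed
    cytoplasmic-particle condition (α = 0.75, D_app = 0.0092 μm² s^−α).

    Attributes
    ----------
    model : str
        One of ``brownian, fbm, rouse, fle_rouse, laplace_walk``.
    alpha : float
        MSD exponent in (0, 2).  For ``brownian`` it is forced to 1; for
        the Rouse models it is the *noise* exponent (free-tracer exponent).
    d_app : float
        Apparent diffusion coefficient, μm² s^−α (2-D convention
        MSD = 4 d_app t^α).
    n_tracks, n_frames : int
        Ensemble size and track length (n_frames >= 2).
    dt : float
        Frame interval, s.
    seed : int or None
        Seed for bit-reproducible output.
    box : float or (float, float) or None
        Side(s) of a rectangular reflecting boundary, μm.
    loc_noise : float
        Localization error s.d. added to every coordinate, μm.
    n_beads : int
        Beads per chain (Rouse models).
    spring_k : float
        Spring relaxation rate constant of the chain, s^-1 (friction 1).
    cv : float
        Coefficient of variation of the per-track diffusivity for
        ``laplace_walk`` (1 = exponential mixing → Laplace steps;
        0 = homogeneous → Gaussian steps).
    """

    model: str = "fbm"
    alpha: float = 0.75
    d_app: float = 0.0092
    n_tracks: int = 2000
    n_frames: int = 500
    dt: float = 0.2
    seed: int | None = None
    box: float | tuple[float, float] | None = None
    loc_noise: float = 0.0
    n_beads: int = 64
    spring_k: float = 2.0
    cv: float = 1.0

    def validate(self):
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {_MODELS}")
        if not (0 < self.alpha < 2):
            raise ValueError("alpha must lie in (0, 2)")
        if self.d_app <= 0:
            raise ValueError("d_app must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.loc_noise < 0:
            raise ValueError("loc_noise must be >= 0")
        if self.box is not None:
            bx, by = self.box_sides()
            if bx <= 0 or by <= 0:
                raise ValueError("box sides must be positive")
            if self.loc_noise and min(bx, by) < self.loc_noise:
                raise ValueError(
                    "box smaller than one localization-noise s.d.; "
                    "confinement would be pure noise"
                )
        return self

    def box_sides(self):
        if self.box is None:
            return None
        if np.isscalar(self.box):
            return float(self.box), float(self.box)
        bx, by = self.box
        return float(bx), float(by)


# ----------------------------------------------------------------------------
# stationary Gaussian sampling
# ----------------------------------------------------------------------------


def fgn_autocovariance(lags, hurst: float) -> np.ndarray:
    """Closed-form autocovariance of unit-variance fGn at integer lags.

    gamma(k) = 0.5 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})
    """
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def _sample_stationary_circulant(acov, size, rng):
    """Sample stationary Gaussian series via circulant embedding.

    Parameters
    ----------
    acov : ndarray, shape (n,)
        Autocovariance at lags 0..n-1.
    size : int
        Number of independent series.

    Returns
    -------
    ndarray of shape (size, n), or None if the embedding is indefinite.
    """
    n = len(acov)
    # circulant row of length 2(n-1) embedding lags 0..n-1
    m = 2 * (n - 1) if n > 1 else 1
    if n == 1:
        return rng.standard_normal((size, 1)) * np.sqrt(acov[0])
    row = np.concatenate([acov, acov[-2:0:-1]])
    lam = np.fft.fft(row).real
    tol = 1e-8 * lam.max()
    if lam.min() < -tol:
        return None  # embedding not nonneg-definite; caller falls back
    lam = np.clip(lam, 0.0, None)
    m = len(row)
    half = m // 2
    a = np.zeros((size, m), dtype=complex)
    a[:, 0] = rng.standard_normal(size) * np.sqrt(lam[0])
    a[:, half] = rng.standard_normal(size) * np.sqrt(lam[half])
    u = rng.standard_normal((size, half - 1))
    v = rng.standard_normal((size, half - 1))
    a[:, 1:half] = (u + 1j * v) * np.sqrt(lam[1:half] / 2.0)
    a[:, half + 1 :] = np.conj(a[:, half - 1 : 0 : -1])
    x = np.fft.fft(a, axis=1) / np.sqrt(m)
    return x[:, :n].real


def _sample_stationary_hosking(acov, size, rng):
    """Durbin–Levinson sequential sampler (exact, O(n^2)).

    Fallback for autocovariances whose circulant embedding is indefinite.
    """
    n = len(acov)
    out = np.empty((size, n))
    sigma2 = acov[0]
    out[:, 0] = rng.standard_normal(size) * np.sqrt(sigma2)
    phi = np.zeros(n)
    for t in range(1, n):
        prev = phi[: t - 1].copy()
        num = acov[t] - prev @ acov[t - 1 : 0 : -1] if t > 1 else acov[1]
        kappa = num / sigma2
        phi[t - 1] = kappa
        if t > 1:
            phi[: t - 1] = prev - kappa * prev[::-1]
        sigma2 = sigma2 * (1.0 - kappa**2)
        if sigma2 < 0:  # numerical guard
            sigma2 = 0.0
        mean = out[:, :t] @ phi[t - 1 :: -1][:t]
        out[:, t] = mean + rng.standard_normal(size) * np.sqrt(sigma2)
    return out


def sample_stationary_gaussian(acov, size, rng, method="auto"):
    """Sample mean-zero stationary Gaussian series with given autocovariance.

    ``method='auto'`` tries circulant embedding (exact, O(n log n)) and
    falls back to the sequential Durbin–Levinson construction when the
    embedding is not non-negative definite.
    """
    acov = np.asarray(acov, dtype=float)
    if method == "hosking":
        return _sample_stationary_hosking(acov, size, rng)
    x = _sample_stationary_circulant(acov, size, rng)
    if x is None:
        if method == "circulant":
            raise ValueError("circulant embedding is not non-negative definite")
        x = _sample_stationary_hosking(acov, size, rng)
    return x


def gen_fgn(n, hurst, dt=1.0, seed=None, *, size=None, rng=None, method="auto"):
    """Fractional Gaussian noise: stationary increments of fBm.

    The cumulative sum of the output has variance ``t**(2*hurst)`` at
    ``t = k*dt`` (standard fBm sampled on a grid of spacing ``dt``).

    Parameters
    ----------
    n : int
        Number of increments (>= 1).
    hurst : float
        Hurst exponent in (0, 1); 0.5 gives white noise.
    dt : float
        Grid spacing; increments are scaled by ``dt**hurst``.
    seed : int, optional
        Seed (ignored if ``rng`` is given).
    size : int, optional
        Number of independent series; if omitted a 1-D array is returned.
    method : {'auto', 'circulant', 'hosking'}

    Returns
    -------
    ndarray, shape (n,) or (size, n)
    """
    if not 0 < hurst < 1:
        raise ValueError("hurst must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    squeeze = size is None
    size = 1 if squeeze else int(size)
    acov = fgn_autocovariance(np.arange(n), hurst)
    x = sample_stationary_gaussian(acov, size, rng, method=method)
    x *= dt**hurst
    return x[0] if squeeze else x


# ----------------------------------------------------------------------------
# track ensembles
# ----------------------------------------------------------------------------


def _reflect(pos, sides):
    """Fold coordinates into [0, L] by specular reflection (period 2L)."""
    out = pos.copy()
    for ax, L in enumerate(sides):
        q = np.mod(out[..., ax], 2 * L)
        out[..., ax] = L - np.abs(q - L)
    return out


def _finalize_positions(disp, config, rng):
    """Cumulate increments, apply boundary and localization noise."""
    n_tracks, n_steps, _ = disp.shape
    pos = np.concatenate(
        [np.zeros((n_tracks, 1, 2)), np.cumsum(disp, axis=1)], axis=1
    )
    sides = config.box_sides()
    if sides is not None:
        start = rng.uniform([0, 0], sides, size=(n_tracks, 2))
        pos = _reflect(pos + start[:, None, :], sides)
    if config.loc_noise:
        pos = pos + rng.normal(0.0, config.loc_noise, size=pos.shape)
    return pos


def sim_tracks(config: SimConfig) -> TrackSet:
    """Generate an ensemble of 2-D tracks according to ``config.model``.

    For ``brownian`` and ``fbm`` the ensemble MSD obeys
    ``E[|r(t) - r(0)|^2] = 4 * d_app * t**alpha`` (each axis contributes
    ``2 * d_app * t**alpha``); confinement and localization noise, when
    configured, are applied after displacement generation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.model == "laplace_walk":
        return sim_laplace_walk(config, rng=rng)
    if config.model in ("rouse", "fle_rouse"):
        noise_exponent = 1.0 if config.model == "rouse" else config.alpha
        return sim_rouse(
            n_beads=config.n_beads,
            dt=config.dt,
            n_steps=config.n_frames,
            noise_exponent=noise_exponent,
            seed=config.seed,
            n_chains=config.n_tracks,
            spring_k=config.spring_k,
            d_free=config.d_app,
        )

    n_inc = config.n_frames - 1
    if config.model == "brownian":
        step_sd = np.sqrt(2.0 * config.d_app * config.dt)
        disp = rng.normal(0.0, step_sd, size=(config.n_tracks, n_inc, 2))
    else:  # fbm
        hurst = config.alpha / 2.0
        fgn = gen_fgn(
            n_inc, hurst, dt=config.dt, rng=rng, size=2 * config.n_tracks
        )
        disp = np.sqrt(2.0 * config.d_app) * fgn.reshape(
            config.n_tracks, 2, n_inc
        ).transpose(0, 2, 1)
    pos = _finalize_positions(disp, config, rng)
    return _positions_to_trackset(pos, config.dt)


def sim_laplace_walk(config: SimConfig, rng=None) -> TrackSet:
    """Brownian tracks with per-track diffusivity mixing (superstatistics).

    Each track gets its own diffusivity drawn from a distribution of mean
    ``d_app`` and coefficient of variation ``config.cv`` (gamma mixing;
    cv = 1 is exponential).  With exponential mixing the pooled 1-D
    single-frame displacements are exactly Laplace distributed, while the
    ensemble MSD remains ``4 * d_app * t``.  ``cv = 0`` degenerates to a
    homogeneous Brownian ensemble (Gaussian steps).
    """
    config.validate()
    if config.cv < 0:
        raise ValueError("cv must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.cv == 0:
        d_track = np.full(config.n_tracks, config.d_app)
    else:
        shape = 1.0 / config.cv**2
        d_track = rng.gamma(shape, config.d_app / shape, size=config.n_tracks)
    n_inc = config.n_frames - 1
    step_sd = np.sqrt(2.0 * d_track * config.dt)
    disp = rng.standard_normal((config.n_tracks, n_inc, 2)) * step_sd[
        :, None, None
    ]
    pos = _finalize_positions(disp, config, rng)
    return _positions_to_trackset(pos, config.dt)


# ----------------------------------------------------------------------------
# Mittag-Leffler function (needed for fractional-Langevin mode relaxation)
# ----------------------------------------------------------------------------


def mittag_leffler_neg(beta: float, x) -> np.ndarray:
    """Evaluate the Mittag-Leffler function E_beta(-x) for x >= 0.

    ``E_beta`` with 0 < beta <= 1 on the negative real axis is completely
    monotone; it interpolates between a stretched exponential at small
    argument and the power law ``x**-1 / Gamma(1-beta)`` at large argument.
    Power series below the crossover, optimally truncated asymptotic series
    above; beta = 1 short-circuits to ``exp(-x)``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    if not 0 < beta <= 1:
        raise ValueError("beta must lie in (0, 1]")
    if beta == 1.0:
        return np.exp(-x)
    out = np.empty_like(x)
    # The power-series terms peak at magnitude ~exp(x**(1/beta)); keep that
    # below ~1e10 so float64 cancellation stays benign, switching to the
    # asymptotic series beyond x = 23**beta.
    crossover = 23.0**beta
    small = x <= crossover
    if np.any(small):
        xs = x[small]
        acc = np.zeros_like(xs)
        term = np.ones_like(xs)
        for k in range(400):
            contrib = term * special.rgamma(beta * k + 1.0)
            acc += contrib
            term = term * (-xs)
            tmax = np.abs(term).max()
            if tmax > 1e280 or np.all(
                tmax * special.rgamma(beta * (k + 1) + 1.0) < 1e-17
            ):
                break
        out[small] = acc
    if np.any(~small):
        xl = x[~small]
        kmax = 50
        terms = np.empty((kmax, xl.size))
        for k in range(1, kmax + 1):
            terms[k - 1] = (
                (-1.0) ** (k + 1) * xl ** (-float(k)) * special.rgamma(1.0 - beta * k)
            )
        # optimal truncation of the divergent asymptotic series: stop at the
        # smallest-magnitude term for each argument
        mags = np.abs(terms)
        mags[mags == 0] = np.inf
        stop = np.argmin(mags, axis=0)
        acc = np.zeros(xl.size)
        for k in range(kmax):
            acc += np.where(k <= stop, terms[k], 0.0)
        out[~small] = acc
    return out


# ----------------------------------------------------------------------------
# Rouse chains
# ----------------------------------------------------------------------------


def _rouse_trackset(beads, com, dt, chain_ids):
    """Assemble bead + centre-of-mass trajectories into one TrackSet.

    ``beads``: (n_chains, n_steps, n_beads, 2); ``com``: (n_chains, n_steps, 2).
    Track ids are ``c{i}_b{j}`` and ``c{i}_com``.
    """
    n_chains, n_steps, n_beads, _ = beads.shape
    frames = np.arange(n_steps)
    recs = []
    for i in range(n_chains):
        cid = chain_ids[i]
        for j in range(n_beads):
            recs.append(
                pd.DataFrame(
                    {
                        "track_id": f"c{cid}_b{j}",
                        "frame": frames,
                        "time_s": frames * dt,
                        "x_um": beads[i, :, j, 0],
                        "y_um": beads[i, :, j, 1],
                    }
                )
            )
        recs.append(
            pd.DataFrame(
                {
                    "track_id": f"c{cid}_com",
                    "frame": frames,
                    "time_s": frames * dt,
                    "x_um": com[i, :, 0],
                    "y_um": com[i, :, 1],
                }
            )
        )
    return TrackSet(pd.concat(recs, ignore_index=True), validate=False)


def middle_bead_ids(n_beads: int, n_chains: int):
    """Track ids of the middle bead of each chain in a sim_rouse TrackSet."""
    return [f"c{i}_b{n_beads // 2}" for i in range(n_chains)]


def com_ids(n_chains: int):
    return [f"c{i}_com" for i in range(n_chains)]


def sim_rouse(
    n_beads: int,
    dt: float,
    n_steps: int,
    noise_exponent: float = 1.0,
    seed: int | None = None,
    *,
    n_chains: int = 1,
    spring_k: float = 2.0,
    d_free: float = 0.01,
    method: str = "auto",
) -> TrackSet:
    """Overdamped bead-spring chain with free ends, in 2-D.

    ``noise_exponent`` (β) is defined through the free (unconnected) bead:
    a free bead in the same medium has per-axis MSD ``2 * d_free * t**β``.

    * β = 1: classic Rouse chain with white thermal noise, integrated by
      Euler–Maruyama from an equilibrium initial configuration.  The middle
      bead shows MSD exponent 1/2 between the fastest-mode and chain
      relaxation times; the centre of mass is Brownian.
    * β < 1: fractional-Langevin Rouse chain (power-law memory friction
      with matching thermal noise).  Simulated *exactly* in normal modes:
      each mode is a stationary Gaussian process with autocorrelation
      ``(kT/λ_p) E_β(−λ_p t^β)`` (Mittag-Leffler) and the centre of mass is
      fBm.  The middle bead shows MSD exponent β/2 at intermediate lags.

    Returns all bead trajectories plus the centre of mass of each chain,
    with track ids ``c{chain}_b{bead}`` and ``c{chain}_com``.
    """
    if n_beads < 8:
        raise ValueError("n_beads must be >= 8")
    if not 0 < noise_exponent <= 1:
        raise ValueError("noise_exponent must lie in (0, 1]")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if dt <= 0 or spring_k <= 0 or d_free <= 0:
        raise ValueError("dt, spring_k and d_free must be positive")
    rng = np.random.default_rng(seed)
    if method == "auto":
        method = "euler" if noise_exponent == 1.0 else "modes"
    if method == "euler":
        if noise_exponent != 1.0:
            raise ValueError(
                "Euler–Maruyama integration is only valid for white noise "
                "(noise_exponent = 1); fractional chains use method='modes'"
            )
        return _sim_rouse_euler(
            n_beads, dt, n_steps, rng, n_chains, spring_k, d_free
        )
    return _sim_rouse_modes(
        n_beads, dt, n_steps, noise_exponent, rng, n_chains, spring_k, d_free
    )


def _sim_rouse_euler(n_beads, dt, n_steps, rng, n_chains, spring_k, d_free):
    # stability of the explicit step: the stiffest mode has rate 4k, so the
    # per-step spring factor 4*k*dt must stay below 1
    if 4.0 * spring_k * dt >= 1.0:
        raise ValueError(
            f"unstable dt: spring term 4*k*dt = {4 * spring_k * dt:.3g} >= 1"
        )
    kT = d_free  # friction coefficient 1 => D_free = kT
    bond_sd = np.sqrt(kT / spring_k)
    # equilibrium initial configuration: Gaussian bonds, centred
    bonds = rng.normal(0.0, bond_sd, size=(n_chains, n_beads - 1, 2))
    x0 = np.concatenate(
        [np.zeros((n_chains, 1, 2)), np.cumsum(bonds, axis=1)], axis=1
    )
    x0 -= x0.mean(axis=1, keepdims=True)
    step_sd = np.sqrt(2.0 * kT * dt)
    beads = np.empty((n_chains, n_steps, n_beads, 2))
    beads[:, 0] = x0
    x = x0.copy()
    for t in range(1, n_steps):
        lap = np.empty_like(x)
        lap[:, 1:-1] = x[:, 2:] - 2 * x[:, 1:-1] + x[:, :-2]
        lap[:, 0] = x[:, 1] - x[:, 0]
        lap[:, -1] = x[:, -2] - x[:, -1]
        x = x + spring_k * dt * lap + rng.normal(0.0, step_sd, size=x.shape)
        beads[:, t] = x
    com = beads.mean(axis=2)
    return _rouse_trackset(beads, com, dt, list(range(n_chains)))


def _sim_rouse_modes(
    n_beads, dt, n_steps, beta, rng, n_chains, spring_k, d_free
):
    """Exact normal-mode realization of the fractional-Langevin Rouse chain."""
    N = n_beads
    kT = d_free * special.gamma(1.0 + beta)  # free bead: MSD = 2 kT t^β / Γ(1+β)
    p = np.arange(1, N)
    lam = 4.0 * spring_k * np.sin(np.pi * p / (2.0 * N)) ** 2
    # orthonormal cosine basis phi_p(n); free-end (Neumann) chain modes
    n_idx = np.arange(N)
    basis = np.sqrt(2.0 / N) * np.cos(
        np.pi * p[:, None] * (n_idx[None, :] + 0.5) / N
    )  # (N-1, N)
    t_lags = (np.arange(n_steps) * dt) ** beta
    nseries = n_chains * 2  # chains x axes
    modes = np.empty((nseries, N - 1, n_steps))
    for j, lam_p in enumerate(lam):
        acov = (kT / lam_p) * mittag_leffler_neg(beta, lam_p * t_lags)
        modes[:, j, :] = sample_stationary_gaussian(acov, nseries, rng)
    # centre-of-mass mode: fBm with per-axis MSD 2*d_free*t^β (free-bead law);
    # x_com = X0/sqrt(N) then has MSD 2*d_free*t^β/N
    fgn = gen_fgn(n_steps - 1, beta / 2.0, dt=dt, rng=rng, size=nseries)
    x0_mode = np.concatenate(
        [np.zeros((nseries, 1)), np.cumsum(np.sqrt(2.0 * d_free) * fgn, axis=1)],
        axis=1,
    )
    # beads: (series, steps, N)
    beads_flat = np.einsum("sjt,jn->stn", modes, basis)
    beads_flat += x0_mode[:, :, None] / np.sqrt(N)
    beads = beads_flat.reshape(n_chains, 2, n_steps, N).transpose(0, 2, 3, 1)
    com = beads.mean(axis=2)
    return _rouse_trackset(beads, com, dt, list(range(n_chains)))


# ----------------------------------------------------------------------------
# movie rendering
# ----------------------------------------------------------------------------


def render_movie(
    tracks: TrackSet,
    psf_sigma: float = 0.13,
    photons_per_spot: float = 2000.0,
    background: float = 10.0,
    pixel_size: float = 0.1,
    seed: int | None = None,
    *,
    shape: tuple[int, int] | None = None,
    shot_noise: bool = True,
) -> Movie:
    """Render a TrackSet as a synthetic fluorescence movie.

    Each emitter is drawn as an integrated 2-D Gaussian PSF (photon count
    per pixel = photons_per_spot × the Gaussian mass falling in the pixel);
    a uniform background is added and, unless ``shot_noise=False``, Poisson
    noise is applied to the expected counts.  Ground-truth emitter
    positions (in px) are stored per frame in the returned Movie.

    Pixel convention: position x (μm) maps to pixel coordinate
    ``x / pixel_size``; integer coordinates are pixel centres.
    """
    if psf_sigma < pixel_size / 2:
        raise ValueError(
            "psf_sigma must be >= pixel_size/2 for a resolvable spot"
        )
    if background < 0 or photons_per_spot <= 0:
        raise ValueError("background >= 0 and photons_per_spot > 0 required")
    rng = np.random.default_rng(seed)
    df = tracks.data
    if len(df):
        frame_interval = tracks.frame_interval() if df["frame"].max() > 0 else 1.0
    else:
        frame_interval = 1.0
    n_frames = int(df["frame"].max()) + 1 if len(df) else 1
    sigma_px = psf_sigma / pixel_size
    if shape is None:
        if len(df):
            w = int(np.ceil(df["x_um"].max() / pixel_size + 6 * sigma_px)) + 1
            h = int(np.ceil(df["y_um"].max() / pixel_size + 6 * sigma_px)) + 1
            shape = (max(h, 8), max(w, 8))
        else:
            shape = (32, 32)
    h, w = shape
    frames = np.full((n_frames, h, w), float(background))
    ground_truth = [[] for _ in range(n_frames)]
    win = int(np.ceil(4 * sigma_px))
    clipped = False
    for row in df.itertuples(index=False):
        f = int(row.frame)
        xc = row.x_um / pixel_size
        yc = row.y_um / pixel_size
        ground_truth[f].append((row.track_id, xc, yc))
        if not (0 <= xc < w and 0 <= yc < h):
            clipped = True
        i0, i1 = int(np.floor(yc)) - win, int(np.floor(yc)) + win + 1
        j0, j1 = int(np.floor(xc)) - win, int(np.floor(xc)) + win + 1
        i0c, i1c = max(i0, 0), min(i1, h)
        j0c, j1c = max(j0, 0), min(j1, w)
        if i0c >= i1c or j0c >= j1c:
            continue
        ii = np.arange(i0c, i1c)
        jj = np.arange(j0c, j1c)
        s2 = np.sqrt(2.0) * sigma_px
        gy = 0.5 * (
            special.erf((ii + 0.5 - yc) / s2) - special.erf((ii - 0.5 - yc) / s2)
        )
        gx = 0.5 * (
            special.erf((jj + 0.5 - xc) / s2) - special.erf((jj - 0.5 - xc) / s2)
        )
        frames[f, i0c:i1c, j0c:j1c] += photons_per_spot * np.outer(gy, gx)
    if clipped:
        warnings.warn(
            "emitter(s) outside the frame were clipped; ground truth retains them",
            stacklevel=2,
        )
    if shot_noise:
        frames = rng.poisson(frames).astype(float)
    gt_frames = [
        pd.DataFrame(g, columns=["track_id", "x_px", "y_px"])
        for g in ground_truth
    ]
    return Movie(
        frames=frames,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        ground_truth=gt_frames,
    )
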