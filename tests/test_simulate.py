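"""Generator correctness: fGn covariance, MSD scaling, confinement,
Laplace-step mixing, Rouse chains, movie rendering, seed determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from subdiff import (
    SimConfig,
    TrackSet,
    compute_ensemble_msd,
    fit_power_law,
    gen_fgn,
    mittag_leffler_neg,
    render_movie,
    sim_laplace_walk,
    sim_rouse,
    sim_tracks,
)
from subdiff.simulate import com_ids, fgn_autocovariance, middle_bead_ids


def _sample_autocov(x, lag):
    if lag == 0:
        return np.mean(x * x)
    return np.mean(x[:, :-lag] * x[:, lag:])


class TestFgn:
    @pytest.mark.parametrize(
        "hurst,rho1",
        [
            (0.5, 0.0),  # white noise
            (0.375, 2 ** (-0.25) - 1),  # ~ -0.159, closed-form fGn rho(1)
            (0.25, 2 ** (-0.5) - 1),  # ~ -0.293
        ],
    )
    def test_lag1_autocorrelation(self, hurst, rho1):
        x = gen_fgn(256, hurst, seed=11, size=800)
        emp = _sample_autocov(x, 1) / _sample_autocov(x, 0)
        se = 3.0 / np.sqrt(x.size)
        assert emp == pytest.approx(rho1, abs=3 * se + 3e-3)

    @pytest.mark.parametrize("method", ["circulant", "hosking"])
    @pytest.mark.parametrize("hurst", [0.25, 0.45, 0.8])
    def test_autocovariance_matches_closed_form(self, method, hurst):
        """Sample autocovariance at lags 0-5 vs the exact fGn formula."""
        n, size = 200, 600
        x = gen_fgn(n, hurst, seed=5, size=size, method=method)
        theo = fgn_autocovariance(np.arange(6), hurst)
        for lag in range(6):
            emp = _sample_autocov(x, lag)
            se = 1.0 / np.sqrt(size * (n - lag))
            # 3 standard errors, inflated for long-memory correlations
            assert abs(emp - theo[lag]) < 3 * 3 * se, (lag, emp, theo[lag])

    def test_cumsum_variance_scales_as_2h(self):
        hurst = 0.35
        x = gen_fgn(128, hurst, dt=0.2, seed=3, size=4000)
        b = np.cumsum(x, axis=1)
        t = np.arange(1, 129) * 0.2
        var = np.mean(b**2, axis=0)
        slope = np.polyfit(np.log(t), np.log(var), 1)[0]
        assert slope == pytest.approx(2 * hurst, abs=0.03)

    def test_invalid_hurst_raises(self):
        for h in (0.0, 1.0, -0.3, 1.5):
            with pytest.raises(ValueError):
                gen_fgn(10, h, seed=0)


class TestMittagLeffler:
    def test_beta_one_is_exp(self):
        x = np.linspace(0, 40, 200)
        assert np.allclose(mittag_leffler_neg(1.0, x), np.exp(-x))

    def test_beta_half_is_scaled_erfc(self):
        # E_{1/2}(-y) = exp(y^2) erfc(y) = erfcx(y)
        y = np.concatenate([np.linspace(0, 12, 300), np.linspace(12, 200, 50)])
        ml = mittag_leffler_neg(0.5, y)
        exact = special.erfcx(y)
        assert np.allclose(ml, exact, rtol=1e-4)

    def test_completely_monotone_and_bounded(self):
        x = np.linspace(0, 100, 2000)
        for beta in (0.3, 0.6, 0.9):
            ml = mittag_leffler_neg(beta, x)
            assert ml[0] == 1.0
            assert np.all(np.diff(ml) <= 1e-10)
            assert np.all((ml >= 0) & (ml <= 1))


class TestSimTracks:
    def test_brownian_msd_at_one_second(self):
        # ensemble mean of |r(1)-r(0)|^2 ~ 4 D t with D = 0.0092
        cfg = SimConfig(
            model="brownian", d_app=0.0092, n_tracks=4000, n_frames=6, dt=0.2, seed=1
        )
        pos = sim_tracks(cfg).to_padded_arrays()
        disp2 = np.sum((pos[:, 5] - pos[:, 0]) ** 2, axis=1)
        expected = 4 * 0.0092 * 1.0
        assert np.mean(disp2) == pytest.approx(
            expected, rel=5 / np.sqrt(len(disp2))
        )

    def test_fbm_log_log_slope(self):
        cfg = SimConfig(
            model="fbm", alpha=0.75, d_app=0.0092, n_tracks=500, n_frames=200,
            dt=0.2, seed=2,
        )
        curve = compute_ensemble_msd(sim_tracks(cfg), max_lag=10.0)
        fit = fit_power_law(curve, (0.2, 10.0))
        assert fit.alpha == pytest.approx(0.75, abs=0.03)

    def test_seed_determinism_bit_identical(self):
        cfg = SimConfig(model="fbm", alpha=0.6, n_tracks=5, n_frames=20, seed=99)
        a = sim_tracks(cfg).to_csv()
        b = sim_tracks(cfg).to_csv()
        assert a == b

    def test_reflecting_box_plateau(self):
        # long-time per-axis displacement variance -> L^2/6 (difference of
        # two independent uniforms on [0, L])
        L = 0.5
        cfg = SimConfig(
            model="brownian", d_app=0.05, n_tracks=3000, n_frames=200, dt=0.2,
            seed=4, box=L,
        )
        ts = sim_tracks(cfg)
        pos = ts.to_padded_arrays()
        assert pos.min() >= 0 and pos.max() <= L
        dx = pos[:, -1, 0] - pos[:, 0, 0]
        assert np.var(dx) == pytest.approx(L**2 / 6, rel=0.1)
        curve = compute_ensemble_msd(ts, max_lag=40.0)
        assert np.all(curve.msd <= 2 * L**2 / 6 * 1.15)

    def test_box_smaller_than_loc_noise_rejected(self):
        cfg = SimConfig(model="brownian", box=0.05, loc_noise=0.1)
        with pytest.raises(ValueError, match="localization-noise"):
            sim_tracks(cfg)

    @pytest.mark.parametrize(
        "field,value",
        [("alpha", 2.5), ("d_app", -1.0), ("n_frames", 1), ("dt", 0.0),
         ("model", "levy")],
    )
    def test_config_validation(self, field, value):
        cfg = SimConfig()
        setattr(cfg, field, value)
        with pytest.raises(ValueError):
            cfg.validate()


class TestLaplaceWalk:
    def test_step_kurtosis_and_peak(self):
        cfg = SimConfig(
            model="laplace_walk", d_app=0.005, n_tracks=6000, n_frames=11,
            dt=0.2, seed=6,
        )
        ts = sim_laplace_walk(cfg)
        pos = ts.to_padded_arrays()
        steps = np.diff(pos[:, :, 0], axis=1).ravel()
        # excess kurtosis of Laplace = 3
        assert stats.kurtosis(steps) == pytest.approx(3.0, abs=0.5)
        z = steps / np.std(steps)
        # unit-variance Laplace density at 0 is 1/sqrt(2)
        dens0 = np.mean(np.abs(z) < 0.05) / 0.1
        assert dens0 == pytest.approx(1 / np.sqrt(2), abs=0.05)

    def test_ensemble_msd_stays_linear(self):
        cfg = SimConfig(
            model="laplace_walk", d_app=0.004, n_tracks=2000, n_frames=100,
            dt=0.2, seed=7,
        )
        curve = compute_ensemble_msd(sim_laplace_walk(cfg), max_lag=10.0)
        fit = fit_power_law(curve, (0.2, 10.0))
        assert fit.alpha == pytest.approx(1.0, abs=0.03)
        assert fit.d_app == pytest.approx(0.004, rel=0.1)

    def test_zero_heterogeneity_is_gaussian(self):
        cfg = SimConfig(
            model="laplace_walk", d_app=0.005, n_tracks=3000, n_frames=11,
            dt=0.2, seed=8, cv=0.0,
        )
        pos = sim_laplace_walk(cfg).to_padded_arrays()
        steps = np.diff(pos[:, :, 0], axis=1).ravel()
        assert stats.kurtosis(steps) == pytest.approx(0.0, abs=0.15)


class TestRouse:
    def test_com_of_classic_rouse_is_brownian(self):
        ts = sim_rouse(
            n_beads=16, dt=0.05, n_steps=2000, noise_exponent=1.0, seed=10,
            n_chains=12, spring_k=2.0, d_free=0.01,
        )
        com = ts.select(com_ids(12))
        fit = fit_power_law(compute_ensemble_msd(com, 20.0), (0.5, 20.0))
        assert fit.alpha == pytest.approx(1.0, abs=0.05)

    def test_middle_bead_classic_exponent_half(self):
        ts = sim_rouse(
            n_beads=64, dt=0.05, n_steps=3000, noise_exponent=1.0, seed=11,
            n_chains=12, spring_k=2.0, d_free=0.01,
        )
        mb = ts.select(middle_bead_ids(64, 12))
        fit = fit_power_law(compute_ensemble_msd(mb, 20.0), (0.5, 20.0))
        assert fit.alpha == pytest.approx(0.5, abs=0.05)

    def test_middle_bead_fractional_exponent_is_half_noise_exponent(self):
        ts = sim_rouse(
            n_beads=64, dt=0.1, n_steps=1500, noise_exponent=0.8, seed=12,
            n_chains=16, spring_k=2.0, d_free=0.01,
        )
        mb = ts.select(middle_bead_ids(64, 16))
        fit = fit_power_law(compute_ensemble_msd(mb, 20.0), (1.0, 20.0))
        assert fit.alpha == pytest.approx(0.4, abs=0.05)

    def test_unstable_dt_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            sim_rouse(n_beads=8, dt=0.2, n_steps=10, noise_exponent=1.0,
                      spring_k=2.0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            sim_rouse(n_beads=4, dt=0.01, n_steps=10)
        with pytest.raises(ValueError):
            sim_rouse(n_beads=8, dt=0.01, n_steps=10, noise_exponent=1.4)


class TestRenderMovie:
    def _single_spot(self, x_px=10.3, y_px=20.7, **kwargs):
        df = pd.DataFrame(
            {"track_id": [0], "frame": [0], "time_s": [0.0],
             "x_um": [x_px * 0.1], "y_um": [y_px * 0.1]}
        )
        defaults = dict(psf_sigma=0.13, photons_per_spot=2000, background=0.0,
                        pixel_size=0.1, shape=(40, 40), shot_noise=False)
        defaults.update(kwargs)
        return render_movie(TrackSet(df), **defaults)

    def test_noise_free_centroid_matches_position(self):
        m = self._single_spot()
        f = m.frames[0]
        ii, jj = np.mgrid[: f.shape[0], : f.shape[1]]
        yc = (f * ii).sum() / f.sum()
        xc = (f * jj).sum() / f.sum()
        assert (xc, yc) == pytest.approx((10.3, 20.7), abs=0.02)

    def test_empty_trackset_gives_background_only(self):
        empty = TrackSet(pd.DataFrame(columns=["track_id", "frame", "time_s",
                                               "x_um", "y_um"]))
        m = render_movie(empty, background=5.0, shot_noise=False)
        assert np.all(m.frames == 5.0)

    def test_frame_sum_matches_photon_budget(self):
        m = self._single_spot(shot_noise=True, seed=2)
        total = m.frames[0].sum()
        assert total == pytest.approx(2000, abs=4 * np.sqrt(2000))

    def test_clipped_emitter_warns_but_stays_in_ground_truth(self):
        with pytest.warns(UserWarning, match="clipped"):
            m = self._single_spot(x_px=-5.0, y_px=2.0)
        assert len(m.ground_truth[0]) == 1

    def test_unresolvable_psf_rejected(self):
        with pytest.raises(ValueError, match="psf_sigma"):
            self._single_spot(psf_sigma=0.01)
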