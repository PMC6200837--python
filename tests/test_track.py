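"""Spot detection and linking against rendered ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from subdiff import SimConfig, TrackSet, link_tracks, render_movie, sim_tracks
from subdiff.track import Detection, detect_movie, detect_spots, track_movie


def render_single(x_px, y_px, n_frames=1, shot_noise=True, seed=1, **kwargs):
    rows = [
        (0, f, float(f), x_px * 0.1, y_px * 0.1) for f in range(n_frames)
    ]
    ts = TrackSet(
        pd.DataFrame(rows, columns=["track_id", "frame", "time_s", "x_um", "y_um"]),
    )
    defaults = dict(psf_sigma=0.13, photons_per_spot=2000, background=10.0,
                    pixel_size=0.1, shape=(48, 48), seed=seed,
                    shot_noise=shot_noise)
    defaults.update(kwargs)
    return render_movie(ts, **defaults)


class TestDetectSpots:
    def test_single_spot_snr10_within_02px(self):
        m = render_single(10.3, 20.7)
        dets = detect_spots(m.frames[0], band_low=1.0, band_high=2.6,
                            threshold=99.8)
        assert len(dets) == 1
        assert np.hypot(dets[0].x - 10.3, dets[0].y - 20.7) < 0.2

    def test_noise_free_bias_below_005px(self):
        for fx, fy in [(0.3, 0.7), (0.5, 0.1), (0.9, 0.4)]:
            m = render_single(15 + fx, 22 + fy, shot_noise=False, background=0.0)
            dets = detect_spots(m.frames[0], band_low=1.0, band_high=2.6,
                                threshold=99.9)
            assert len(dets) == 1
            assert np.hypot(dets[0].x - (15 + fx), dets[0].y - (22 + fy)) < 0.05

    def test_blank_frame_no_detections(self):
        rng = np.random.default_rng(2)
        frame = rng.poisson(10.0, size=(48, 48)).astype(float)
        dets = detect_spots(frame, band_low=1.0, band_high=2.6, threshold=200,
                            threshold_mode="absolute")
        assert dets == []

    def test_constant_frame_warns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            dets = detect_spots(np.full((32, 32), 7.0), band_low=1.0,
                                band_high=2.6)
        assert dets == []

    def test_two_spots_resolved(self):
        rows = [(0, 0, 0.0, 1.0, 2.0), (1, 0, 0.0, 2.0, 2.0)]  # 10 px apart
        ts = TrackSet(pd.DataFrame(
            rows, columns=["track_id", "frame", "time_s", "x_um", "y_um"]))
        m = render_movie(ts, psf_sigma=0.13, photons_per_spot=2000,
                         background=10.0, pixel_size=0.1, shape=(40, 40), seed=3)
        dets = detect_spots(m.frames[0], band_low=1.0, band_high=2.6,
                            threshold=99.7)
        assert len(dets) == 2
        gt = m.ground_truth[0][["x_px", "y_px"]].to_numpy()
        d, _ = cKDTree(gt).query([[p.x, p.y] for p in dets])
        assert np.all(d < 0.2)

    def test_band_order_validated(self):
        with pytest.raises(ValueError, match="band_low"):
            detect_spots(np.zeros((32, 32)), band_low=3.0, band_high=1.0)


def _d(frame, x, y):
    return Detection(frame=frame, x=x, y=y, intensity=1.0, width=1.0)


class TestLinkTracks:
    def test_single_emitter_single_track(self):
        m = render_single(20.0, 20.0, n_frames=100)
        ts = track_movie(m, band_low=1.0, band_high=2.6, threshold=99.8,
                         min_length=20)
        assert ts.n_tracks == 1
        assert len(ts.data) == 100

    def test_min_length_filters_short_movies(self):
        m = render_single(20.0, 20.0, n_frames=40)
        ts = track_movie(m, band_low=1.0, band_high=2.6, threshold=99.8,
                         min_length=50)
        assert ts.n_tracks == 0

    def test_gap_bridging_with_memory(self):
        dets = [[_d(0, 5.0, 5.0)], [], [_d(2, 5.3, 5.1)]]
        ts0 = link_tracks(dets, max_disp=2.0, memory=0, min_length=1)
        ts1 = link_tracks(dets, max_disp=2.0, memory=1, min_length=1)
        assert ts0.n_tracks == 2
        assert ts1.n_tracks == 1

    def test_equidistant_tie_break_is_deterministic(self):
        dets = [[_d(0, 5.0, 5.0)], [_d(1, 4.0, 5.0), _d(1, 6.0, 5.0)]]
        out = [link_tracks(dets, max_disp=3.0, min_length=1).to_csv()
               for _ in range(3)]
        assert out[0] == out[1] == out[2]
        # lower detection index wins the tie
        ts = link_tracks(dets, max_disp=3.0, min_length=2)
        tid = ts.data.loc[ts.data["frame"] == 0, "track_id"].iloc[0]
        linked = ts.data[(ts.data["track_id"] == tid) & (ts.data["frame"] == 1)]
        assert linked["x_um"].iloc[0] == pytest.approx(4.0)

    def test_physical_unit_conversion(self):
        dets = [[_d(0, 10.0, 20.0)], [_d(1, 11.0, 20.0)]]
        ts = link_tracks(dets, max_disp=3.0, min_length=2, pixel_size=0.1,
                         frame_interval=0.2)
        assert ts.data["x_um"].tolist() == pytest.approx([1.0, 1.1])
        assert ts.data["time_s"].tolist() == pytest.approx([0.0, 0.2])

    def test_link_identity_audit_low_density(self):
        """>= 99% of frame-to-frame links match ground-truth identities for
        well separated Brownian emitters."""
        n_emit = 36
        cfg = SimConfig(model="brownian", d_app=0.003, n_tracks=n_emit,
                        n_frames=60, dt=0.2, seed=8)
        sim = sim_tracks(cfg)
        df = sim.data.copy()
        gx = (np.arange(n_emit) % 6) * 2.0 + 1.0
        gy = (np.arange(n_emit) // 6) * 2.0 + 1.0
        df["x_um"] += df["track_id"].map(lambda i: gx[i])
        df["y_um"] += df["track_id"].map(lambda i: gy[i])
        m = render_movie(TrackSet(df), psf_sigma=0.13, photons_per_spot=3000,
                         background=10.0, pixel_size=0.1, shape=(140, 140),
                         seed=9)
        dets = detect_movie(m, band_low=1.0, band_high=2.6, threshold=99.0)
        linked = link_tracks(dets, max_disp=5.0, min_length=20,
                             pixel_size=m.pixel_size,
                             frame_interval=m.frame_interval)
        good = bad = 0
        for _, g in linked:
            px = g[["x_um", "y_um"]].to_numpy() / m.pixel_size
            ids = []
            for f, p in zip(g["frame"], px):
                gt = m.ground_truth[int(f)]
                d = np.hypot(gt["x_px"] - p[0], gt["y_px"] - p[1])
                ids.append(gt["track_id"].iloc[int(np.argmin(d))])
            same = np.array(ids[:-1]) == np.array(ids[1:])
            good += int(same.sum())
            bad += int((~same).sum())
        assert good / (good + bad) >= 0.99
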