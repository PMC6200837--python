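import numpy as np
import pandas as pd
import pytest

from subdiff import TrackSet


@pytest.fixture
def hand_track():
    """The three-point track (0,0), (1,0), (1,1) at dt = 1 s."""
    return TrackSet(
        pd.DataFrame(
            {
                "track_id": [0, 0, 0],
                "frame": [0, 1, 2],
                "time_s": [0.0, 1.0, 2.0],
                "x_um": [0.0, 1.0, 1.0],
                "y_um": [0.0, 0.0, 1.0],
            }
        )
    )


@pytest.fixture
def toy_tracks():
    """Five short random tracks of unequal length at dt = 0.5 s."""
    rng = np.random.default_rng(7)
    rows = []
    for tid, length in enumerate([5, 8, 3, 6, 4]):
        x = np.cumsum(rng.normal(size=length))
        y = np.cumsum(rng.normal(size=length))
        for k in range(length):
            rows.append((tid, k, 0.5 * k, x[k], y[k]))
    return TrackSet(
        pd.DataFrame(
            rows, columns=["track_id", "frame", "time_s", "x_um", "y_um"]
        )
    )


def brute_force_msd(tracks: TrackSet, max_lag: float):
    """Independent oracle: double loop over all tracks and start times."""
    dt = tracks.frame_interval()
    sums, counts = {}, {}
    for _, g in tracks:
        x = g["x_um"].to_numpy()
        y = g["y_um"].to_numpy()
        f = g["frame"].to_numpy()
        n = len(g)
        for i in range(n):
            for j in range(i + 1, n):
                k = f[j] - f[i]
                if k * dt > max_lag + 1e-9:
                    continue
                sq = (x[j] - x[i]) ** 2 + (y[j] - y[i]) ** 2
                sums[k] = sums.get(k, 0.0) + sq
                counts[k] = counts.get(k, 0) + 1
    ks = sorted(sums)
    lags = np.array([k * dt for k in ks])
    msd = np.array([sums[k] / counts[k] for k in ks])
    n_pairs = np.array([counts[k] for k in ks])
    return lags, msd, n_pairs


def exact_power_law_curve(alpha, d_app, lags):
    """Noiseless MSD curve msd = 4 d_app lag^alpha."""
    from subdiff import MSDCurve

    lags = np.asarray(lags, dtype=float)
    return MSDCurve(lags, 4.0 * d_app * lags**alpha, np.ones_like(lags, dtype=int))
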