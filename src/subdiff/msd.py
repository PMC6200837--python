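"""Ensemble-averaged MSD computation and power-law fitting.

The 2-D ensemble-and-time-averaged mean-squared displacement

    MSD(τ) = < |r(t+τ) − r(t)|² >   over all tracks and start times

is fitted to the anomalous-diffusion law MSD = 4 D_app τ^α by ordinary
least squares of log10(MSD) on log10(τ), with 95% confidence intervals
from the regression t-distribution.  ``PowerLawMSD`` is a scikit-learn
estimator (``fit(lags, msd)`` → ``alpha_``, ``d_app_``, …); the module
functions are thin wrappers producing the frozen :class:`PowerLawFit`
record used throughout the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .trackset import TrackSet

__all__ = [
    "MSDCurve",
    "PowerLawFit",
    "PowerLawMSD",
    "compute_ensemble_msd",
    "fit_power_law",
    "fit_two_segment",
]


@dataclass
class MSDCurve:
    """Ensemble-averaged MSD versus lag time.

    Attributes
    ----------
    lags : ndarray
        Lag times in s, strictly increasing, all positive.
    msd : ndarray
        MSD values in μm², all >= 0.
    n_pairs : ndarray
        Number of (track, start-time) displacement pairs averaged per lag.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (len(self.lags) == len(self.msd) == len(self.n_pairs)):
            raise ValueError("lags, msd, n_pairs must have equal length")
        if np.any(self.lags <= 0):
            raise ValueError("lags must be positive")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")
        if np.any(self.n_pairs < 1):
            raise ValueError("every reported lag needs n_pairs >= 1")

    def to_csv(self, path_or_buf=None, sep=","):
        df = pd.DataFrame(
            {"lag_s": self.lags, "msd_um2": self.msd, "n_pairs": self.n_pairs}
        )
        return df.to_csv(path_or_buf, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, sep=",") -> "MSDCurve":
        df = pd.read_csv(path_or_buf, sep=sep)
        return cls(df["lag_s"], df["msd_um2"], df["n_pairs"])


@dataclass
class PowerLawFit:
    """Result of fitting MSD = 4 D_app τ^α in log-log space.

    ``alpha_ci`` and ``d_app_ci`` are 95% confidence *half*-intervals.
    """

    alpha: float
    d_app: float
    alpha_ci: float
    d_app_ci: float
    lag_window: tuple[float, float]
    r_squared: float
    n_lags: int = 0

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path_or_str) -> "PowerLawFit":
        try:
            d = json.loads(path_or_str)
        except (json.JSONDecodeError, TypeError):
            with open(path_or_str) as fh:
                d = json.load(fh)
        d["lag_window"] = tuple(d["lag_window"])
        return cls(**d)


def compute_ensemble_msd(tracks: TrackSet, max_lag: float) -> MSDCurve:
    """Time-and-ensemble-averaged 2-D MSD of a uniformly sampled TrackSet.

    For each lag τ = k·dt up to ``max_lag``, averages |r(t+τ) − r(t)|² over
    every track and every admissible start time.  Requires a uniform frame
    interval across tracks (raises naming the offending track otherwise).
    """
    dt = tracks.frame_interval()
    pos = tracks.to_padded_arrays()  # (n_tracks, n_frames, 2), NaN-padded
    n_frames = pos.shape[1]
    k_max = min(int(np.floor(max_lag / dt + 1e-9)), n_frames - 1)
    if k_max < 1:
        raise ValueError("max_lag shorter than one frame interval")
    lags, msd, n_pairs = [], [], []
    for k in range(1, k_max + 1):
        d = pos[:, k:, :] - pos[:, :-k, :]
        sq = d[..., 0] ** 2 + d[..., 1] ** 2
        n = int(np.sum(~np.isnan(sq)))
        if n == 0:
            continue
        lags.append(k * dt)
        msd.append(float(np.nanmean(sq)))
        n_pairs.append(n)
    return MSDCurve(np.array(lags), np.array(msd), np.array(n_pairs))


class PowerLawMSD(RegressorMixin, BaseEstimator):
    """Power-law MSD regression, scikit-learn style.

    Ordinary least squares of log10(MSD) on log10(lag) inside
    ``[lag_min, lag_max]``; all lags in the window enter unweighted.
    The slope is the anomalous exponent α and the intercept gives
    D_app = 10^intercept / 4 (2-D convention).  Confidence intervals use
    the regression t-distribution at ``level``.

    Parameters
    ----------
    lag_min, lag_max : float
        Fit window in s (defaults: one frame at 5 fps to 10 s, the window
        that avoids ballistic contamination at long lags).
    level : float
        Confidence level for the reported half-intervals.

    Attributes
    ----------
    alpha_ : float
        Fitted exponent (slope).
    d_app_ : float
        Apparent diffusion coefficient, μm² s^−α.
    alpha_ci_, d_app_ci_ : float
        Confidence half-intervals at ``level``.
    r_squared_ : float
    lag_window_ : tuple of float
        Actual (min, max) lag used.
    n_lags_ : int
    """

    def __init__(self, lag_min: float = 0.2, lag_max: float = 10.0, level: float = 0.95):
        self.lag_min = lag_min
        self.lag_max = lag_max
        self.level = level

    def fit(self, X, y=None):
        """Fit on an :class:`MSDCurve`, or on arrays ``X=lags, y=msd``."""
        if isinstance(X, MSDCurve):
            lags, msd = X.lags, X.msd
        else:
            lags = np.asarray(X, dtype=float).ravel()
            msd = np.asarray(y, dtype=float).ravel()
        sel = (lags >= self.lag_min - 1e-12) & (lags <= self.lag_max + 1e-12)
        lags, msd = lags[sel], msd[sel]
        if len(lags) < 3:
            raise ValueError(
                f"need >= 3 lags inside window [{self.lag_min}, {self.lag_max}]"
            )
        if np.any(msd <= 0):
            raise ValueError("msd <= 0 inside fit window: log undefined")
        res = stats.linregress(np.log10(lags), np.log10(msd))
        n = len(lags)
        tcrit = stats.t.ppf(0.5 + self.level / 2.0, n - 2)
        self.alpha_ = float(res.slope)
        self.alpha_ci_ = float(tcrit * res.stderr)
        self.d_app_ = float(10.0**res.intercept / 4.0)
        ic_lo = 10.0 ** (res.intercept - tcrit * res.intercept_stderr) / 4.0
        ic_hi = 10.0 ** (res.intercept + tcrit * res.intercept_stderr) / 4.0
        self.d_app_ci_ = float((ic_hi - ic_lo) / 2.0)
        self.r_squared_ = float(res.rvalue**2)
        self.lag_window_ = (float(lags.min()), float(lags.max()))
        self.n_lags_ = n
        return self

    def predict(self, X):
        """MSD values of the fitted law at the given lags."""
        check_is_fitted(self, "alpha_")
        lags = np.asarray(X, dtype=float).ravel()
        return 4.0 * self.d_app_ * lags**self.alpha_

    def to_result(self) -> PowerLawFit:
        check_is_fitted(self, "alpha_")
        return PowerLawFit(
            alpha=self.alpha_,
            d_app=self.d_app_,
            alpha_ci=self.alpha_ci_,
            d_app_ci=self.d_app_ci_,
            lag_window=self.lag_window_,
            r_squared=self.r_squared_,
            n_lags=self.n_lags_,
        )


def fit_power_law(curve: MSDCurve, lag_window=(0.2, 10.0), level=0.95) -> PowerLawFit:
    """Fit MSD = 4 D_app τ^α over ``lag_window``; see :class:`PowerLawMSD`."""
    lo, hi = lag_window
    est = PowerLawMSD(lag_min=lo, lag_max=hi, level=level).fit(curve)
    return est.to_result()


def fit_two_segment(
    curve: MSDCurve, break_lag: float, level=0.95
) -> tuple[PowerLawFit, PowerLawFit]:
    """Independent power-law fits below and above ``break_lag``.

    The break lag itself is included in the early window.  Raises if either
    side holds fewer than 3 lags.
    """
    lo, hi = float(curve.lags.min()), float(curve.lags.max())
    if not lo < break_lag < hi:
        raise ValueError(
            f"break_lag {break_lag} outside curve lag range [{lo}, {hi}]"
        )
    n_early = int(np.sum(curve.lags <= break_lag))
    n_late = int(np.sum(curve.lags > break_lag))
    if n_early < 3 or n_late < 3:
        raise ValueError(
            f"need >= 3 lags on each side of the break "
            f"(got {n_early} early, {n_late} late)"
        )
    early = fit_power_law(curve, (lo, break_lag), level=level)
    eps = np.min(np.diff(curve.lags)) / 2.0
    late = fit_power_law(curve, (break_lag + eps, hi), level=level)
    return early, late
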