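"""Core data containers for single-particle-tracking data.

The central currency of the pipeline is the :class:`TrackSet`: a collection
of time-ordered 2-D trajectories in physical units (positions in μm, times
in s), backed by a pandas DataFrame with the canonical track-table columns
``track_id, frame, time_s, x_um, y_um``.  :class:`Movie` carries a stack of
2-D intensity frames together with the pixel size and frame interval needed
to convert detections back to physical units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["track_id", "frame", "time_s", "x_um", "y_um"]


class TrackSet:
    """Collection of time-ordered 2-D trajectories in physical units.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per localization with columns ``track_id`` (identifier),
        ``frame`` (non-negative integer, strictly increasing within a
        track), ``time_s`` (seconds), ``x_um``, ``y_um`` (micrometres).

    Notes
    -----
    Validation enforces strictly increasing times within each track and
    finite coordinates.  Rows are stored sorted by (track_id, frame).
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        missing = [c for c in TRACK_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"track table missing columns: {missing}")
        data = data[TRACK_COLUMNS].copy()
        data.sort_values(["track_id", "frame"], inplace=True, kind="stable")
        data.reset_index(drop=True, inplace=True)
        if validate and len(data):
            xy = data[["x_um", "y_um", "time_s"]].to_numpy(float)
            if not np.all(np.isfinite(xy)):
                raise ValueError("non-finite coordinate or time in track table")
            g = data.groupby("track_id", sort=False)
            dt = g["time_s"].diff().dropna()
            if not (dt > 0).all():
                bad = data.loc[dt.index[dt <= 0], "track_id"].iloc[0]
                raise ValueError(
                    f"times not strictly increasing within track {bad!r}"
                )
            dframe = g["frame"].diff().dropna()
            if not (dframe > 0).all():
                bad = data.loc[dframe.index[dframe <= 0], "track_id"].iloc[0]
                raise ValueError(
                    f"frames not strictly increasing within track {bad!r}"
                )
        self.data = data

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return int(self.data["track_id"].nunique())

    @property
    def n_tracks(self) -> int:
        return len(self)

    @property
    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    def __iter__(self):
        """Yield (track_id, sub-DataFrame) pairs."""
        return iter(self.data.groupby("track_id", sort=False))

    def select(self, ids) -> "TrackSet":
        """Subset by track id(s)."""
        ids = np.atleast_1d(ids)
        return TrackSet(
            self.data[self.data["track_id"].isin(ids)], validate=False
        )

    # -- time base ---------------------------------------------------------
    def frame_interval(self) -> float:
        """Uniform sampling interval in s.

        Raises
        ------
        ValueError
            If any track is non-uniformly sampled (names the track).
        """
        dt_ref = None
        for tid, g in self:
            t = g["time_s"].to_numpy(float)
            if len(t) < 2:
                continue
            dts = np.diff(t)
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
                raise ValueError(f"non-uniform sampling within track {tid!r}")
            if dt_ref is None:
                dt_ref = dts[0]
            elif not np.isclose(dts[0], dt_ref, rtol=1e-6):
                raise ValueError(
                    f"track {tid!r} has frame interval {dts[0]:g} s, "
                    f"others use {dt_ref:g} s"
                )
        if dt_ref is None:
            raise ValueError("no track with >= 2 points")
        return float(dt_ref)

    def to_padded_arrays(self):
        """Positions on a common frame grid, NaN-padded.

        Returns
        -------
        pos : ndarray, shape (n_tracks, n_frames, 2)
            ``pos[i, k]`` is the (x, y) position of track i at frame index
            ``k + frame_offset[i]``; NaN where the track has no point.
            Each track is aligned to start at index 0 (only relative lags
            matter for MSD/step statistics).
        """
        groups = list(self)
        n_tracks = len(groups)
        max_len = 0
        spans = []
        for _, g in groups:
            f = g["frame"].to_numpy(int)
            spans.append(f - f[0])
            max_len = max(max_len, spans[-1][-1] + 1)
        pos = np.full((n_tracks, max_len, 2), np.nan)
        for i, ((_, g), rel) in enumerate(zip(groups, spans)):
            pos[i, rel, 0] = g["x_um"].to_numpy(float)
            pos[i, rel, 1] = g["y_um"].to_numpy(float)
        return pos

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path_or_buf=None, sep: str = ","):
        """Write the track table as delimited text with a header row."""
        return self.data.to_csv(path_or_buf, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, sep: str = ",") -> "TrackSet":
        df = pd.read_csv(path_or_buf, sep=sep)
        return cls(df)

    @classmethod
    def from_arrays(cls, track_ids, frames, times, x, y) -> "TrackSet":
        return cls(
            pd.DataFrame(
                {
                    "track_id": np.asarray(track_ids),
                    "frame": np.asarray(frames, dtype=int),
                    "time_s": np.asarray(times, dtype=float),
                    "x_um": np.asarray(x, dtype=float),
                    "y_um": np.asarray(y, dtype=float),
                }
            )
        )

    def __repr__(self) -> str:
        return (
            f"TrackSet(n_tracks={self.n_tracks}, "
            f"n_localizations={len(self.data)})"
        )


def _positions_to_trackset(positions: np.ndarray, dt: float) -> TrackSet:
    """Build a TrackSet from an array of shape (n_tracks, n_frames, 2)."""
    n_tracks, n_frames, _ = positions.shape
    ids = np.repeat(np.arange(n_tracks), n_frames)
    frames = np.tile(np.arange(n_frames), n_tracks)
    df = pd.DataFrame(
        {
            "track_id": ids,
            "frame": frames,
            "time_s": frames * dt,
            "x_um": positions[:, :, 0].ravel(),
            "y_um": positions[:, :, 1].ravel(),
        }
    )
    return TrackSet(df, validate=False)


@dataclass
class Movie:
    """Stack of 2-D intensity frames with acquisition metadata.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Non-negative intensities (photon counts).
    pixel_size : float
        μm per pixel.
    frame_interval : float
        s per frame.
    ground_truth : list of DataFrame or None
        Optional per-frame emitter positions (columns ``track_id, x_px,
        y_px``) recorded by the renderer.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    ground_truth: list | None = field(default=None, repr=False)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, h, w) stack")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape[1:]

    def to_tiff(self, path: str):
        """Write a multi-page TIFF plus a plain-text key=value sidecar."""
        import tifffile

        tifffile.imwrite(
            path, self.frames.astype(np.float32), photometric="minisblack"
        )
        with open(_sidecar_path(path), "w") as fh:
            fh.write(f"pixel_size_um={self.pixel_size!r}\n")
            fh.write(f"frame_interval_s={self.frame_interval!r}\n")

    @classmethod
    def from_tiff(cls, path: str) -> "Movie":
        import tifffile

        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        meta = {}
        sidecar = _sidecar_path(path)
        if os.path.exists(sidecar):
            with open(sidecar) as fh:
                for line in fh:
                    line = line.strip()
                    if line and not line.startswith("#") and "=" in line:
                        k, v = line.split("=", 1)
                        meta[k.strip()] = float(v)
        return cls(
            frames=frames,
            pixel_size=meta.get("pixel_size_um", 1.0),
            frame_interval=meta.get("frame_interval_s", 1.0),
        )


def _sidecar_path(path: str) -> str:
    base, _ = os.path.splitext(path)
    return base + ".meta.txt"
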