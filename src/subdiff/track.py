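"""Spot detection and trajectory linking for fluorescence movies.

Detection: difference-of-Gaussians bandpass, local-maxima candidates above
an intensity threshold, then subpixel refinement by intensity-weighted
centroid (one re-centering pass) in a window of radius ``band_high``.
Linking: greedy mutual-nearest-neighbour assignment between consecutive
frames within ``max_disp``, optional gap bridging over ``memory`` frames,
and a minimum track length filter.  Positions are converted to physical
units with the movie metadata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .trackset import Movie, TrackSet

__all__ = ["Detection", "detect_spots", "detect_movie", "link_tracks", "track_movie"]

logger = logging.getLogger(__name__)


@dataclass
class Detection:
    """One localized spot in one frame.

    Positions are in px with the origin at the centre of pixel (0, 0).
    """

    frame: int
    x: float
    y: float
    intensity: float  # summed bandpassed counts in the refinement window
    width: float  # r.m.s. spot radius in px


def _centroid(img, yc, xc, radius):
    """Intensity-weighted centroid in a clipped square window; returns
    (y, x, mass, width) with negative bandpass values clipped to zero."""
    h, w = img.shape
    i0, i1 = max(yc - radius, 0), min(yc + radius + 1, h)
    j0, j1 = max(xc - radius, 0), min(xc + radius + 1, w)
    win = np.clip(img[i0:i1, j0:j1], 0.0, None)
    mass = win.sum()
    if mass <= 0:
        return float(yc), float(xc), 0.0, 0.0
    ii, jj = np.mgrid[i0:i1, j0:j1]
    y = float((win * ii).sum() / mass)
    x = float((win * jj).sum() / mass)
    var = float((win * ((ii - y) ** 2 + (jj - x) ** 2)).sum() / mass)
    return y, x, float(mass), float(np.sqrt(var / 2.0))


def detect_spots(
    frame: np.ndarray,
    band_low: float = 1.0,
    band_high: float = 3.0,
    threshold: float = 99.5,
    threshold_mode: str = "percentile",
) -> list[Detection]:
    """Detect spots in a single 2-D intensity frame.

    Parameters
    ----------
    frame : ndarray
        2-D intensity array.
    band_low, band_high : float
        Gaussian sigmas (px) of the difference-of-Gaussians bandpass;
        ``band_high`` also sets the refinement window radius.  A good
        default for ``band_high`` is twice the PSF sigma in px.
    threshold : float
        Candidate threshold on the bandpassed image: a percentile
        (``threshold_mode='percentile'``, default 99.5) or absolute counts
        (``threshold_mode='absolute'``).

    Returns
    -------
    list of Detection, sorted by decreasing intensity.
    """
    frame = np.asarray(frame, dtype=float)
    if band_low >= band_high:
        raise ValueError("band_low must be < band_high")
    if min(frame.shape) < 2 * band_high:
        raise ValueError("frame must be at least 2*band_high wide")
    if frame.max() == frame.min():
        warnings.warn("constant frame: no spots detectable", stacklevel=2)
        return []
    bp = ndimage.gaussian_filter(frame, band_low) - ndimage.gaussian_filter(
        frame, band_high
    )
    if threshold_mode == "percentile":
        thr = np.percentile(bp, threshold)
    elif threshold_mode == "absolute":
        thr = threshold
    else:
        raise ValueError("threshold_mode must be 'percentile' or 'absolute'")
    size = 2 * int(np.ceil(band_high)) + 1
    maxima = (bp == ndimage.maximum_filter(bp, size=size)) & (bp > thr)
    radius = int(np.ceil(band_high))
    dets = []
    for yc, xc in zip(*np.nonzero(maxima)):
        y, x, mass, width = _centroid(bp, yc, xc, radius)
        # one re-centering pass: recompute around the refined position
        y, x, mass, width = _centroid(bp, int(round(y)), int(round(x)), radius)
        if mass <= 0:
            continue
        dets.append(Detection(frame=-1, x=x, y=y, intensity=mass, width=width))
    dets.sort(key=lambda d: -d.intensity)
    return dets


def detect_movie(movie: Movie, **kwargs) -> list[list[Detection]]:
    """Run :func:`detect_spots` on every frame; logs per-frame counts."""
    out = []
    for f in range(movie.n_frames):
        dets = detect_spots(movie.frames[f], **kwargs)
        for d in dets:
            d.frame = f
        logger.debug("frame %d: %d detections", f, len(dets))
        out.append(dets)
    return out


class _OpenTrack:
    __slots__ = ("points", "last_frame")

    def __init__(self, frame, det):
        self.points = [(frame, det)]
        self.last_frame = frame

    def add(self, frame, det):
        self.points.append((frame, det))
        self.last_frame = frame


def _mutual_nn_links(ends, dets, max_disp):
    """Greedy mutual-nearest-neighbour pairing within max_disp.

    Ties are broken deterministically by lower detection index (argmin).
    Returns list of (track_index, det_index).
    """
    if not len(ends) or not len(dets):
        return []
    d2 = (
        (ends[:, None, 0] - dets[None, :, 0]) ** 2
        + (ends[:, None, 1] - dets[None, :, 1]) ** 2
    )
    d2 = np.where(d2 <= max_disp**2, d2, np.inf)
    links = []
    alive_t = np.ones(len(ends), dtype=bool)
    alive_d = np.ones(len(dets), dtype=bool)
    while True:
        nn_of_t = np.argmin(d2, axis=1)  # ties -> lowest detection index
        nn_of_d = np.argmin(d2, axis=0)
        made = False
        for ti in np.nonzero(alive_t)[0]:
            di = nn_of_t[ti]
            if not np.isfinite(d2[ti, di]):
                continue
            if nn_of_d[di] == ti:  # mutual
                links.append((int(ti), int(di)))
                d2[ti, :] = np.inf
                d2[:, di] = np.inf
                alive_t[ti] = False
                alive_d[di] = False
                made = True
        if not made:
            return links


def link_tracks(
    detections: list[list[Detection]],
    max_disp: float = 5.0,
    memory: int = 0,
    min_length: int = 20,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
) -> TrackSet:
    """Link per-frame detections into trajectories.

    Parameters
    ----------
    detections : list of list of Detection
        One list per frame (as returned by :func:`detect_movie`).
    max_disp : float
        Maximum frame-to-frame displacement, px.
    memory : int
        Number of consecutive frames a particle may vanish and still be
        re-linked.
    min_length : int
        Minimum number of localizations for a track to be kept.
    pixel_size, frame_interval : float
        Conversion to μm and s for the output TrackSet.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    if memory < 0:
        raise ValueError("memory must be >= 0")
    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    for f, dets in enumerate(detections):
        active = [tr for tr in open_tracks if f - tr.last_frame <= memory + 1]
        expired = [tr for tr in open_tracks if f - tr.last_frame > memory + 1]
        closed.extend(expired)
        linked_dets = set()
        if active and dets:
            ends = np.array(
                [[tr.points[-1][1].x, tr.points[-1][1].y] for tr in active]
            )
            pts = np.array([[d.x, d.y] for d in dets])
            for ti, di in _mutual_nn_links(ends, pts, max_disp):
                active[ti].add(f, dets[di])
                linked_dets.add(di)
        for di, d in enumerate(dets):
            if di not in linked_dets:
                active.append(_OpenTrack(f, d))
        open_tracks = active
    closed.extend(open_tracks)
    rows = []
    tid = 0
    for tr in closed:
        if len(tr.points) < min_length:
            continue
        for f, d in tr.points:
            rows.append(
                (tid, f, f * frame_interval, d.x * pixel_size, d.y * pixel_size)
            )
        tid += 1
    df = pd.DataFrame(
        rows, columns=["track_id", "frame", "time_s", "x_um", "y_um"]
    )
    return TrackSet(df, validate=False)


def track_movie(
    movie: Movie,
    band_low: float = 1.0,
    band_high: float = 3.0,
    threshold: float = 99.5,
    threshold_mode: str = "percentile",
    max_disp: float = 5.0,
    memory: int = 0,
    min_length: int = 20,
) -> TrackSet:
    """Detect and link in one call, using the movie's physical metadata."""
    dets = detect_movie(
        movie,
        band_low=band_low,
        band_high=band_high,
        threshold=threshold,
        threshold_mode=threshold_mode,
    )
    return link_tracks(
        dets,
        max_disp=max_disp,
        memory=memory,
        min_length=min_length,
        pixel_size=movie.pixel_size,
        frame_interval=movie.frame_interval,
    )
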