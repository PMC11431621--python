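"""Preprocessing of planar animal tracks into angular coordinates.

Input is TRex-style tabular tracking output: per-frame centroid and head
positions of each animal, at a fixed frame rate (40 fps for the shiner
recordings), with occasional frames missing where the tracker failed.
The pipeline re-centres coordinates on the middle of the (annular) tank,
converts to polar coordinates, derives each animal's heading from the
centroid-to-head vector, repairs spurious ~180-degree head/tail
identification flips, computes pairwise alignment angles, and estimates
the drift-diffusion parameters (Omega, sigma) from the wrapped angular
increments.

Missing frames are masked and dropped, never interpolated; paired
operations drop a frame if either member is masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi

#: default head/tail flip threshold, radians (a near-pi heading jump
#: between consecutive frames is treated as a tracking artefact)
FLIP_THRESHOLD = np.pi - 0.6

__all__ = [
    "PlanarTrack",
    "PolarTrack",
    "AlignmentSeries",
    "to_polar",
    "heading",
    "fix_heading_flips",
    "alignment",
    "rolling_mean",
    "estimate_drift_noise",
    "wrapped_diff",
    "FLIP_THRESHOLD",
]


@dataclass
class PlanarTrack:
    """Per-frame centroid and head positions of one animal, in cm.

    ``valid`` masks frames the tracker missed; masked frames carry no
    position requirements (NaN is typical).
    """

    frame: np.ndarray
    centroid: np.ndarray  # (n, 2)
    head: np.ndarray      # (n, 2)
    fps: float = 40.0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame)
        self.centroid = np.asarray(self.centroid, float)
        self.head = np.asarray(self.head, float)
        if np.any(np.diff(self.frame) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.centroid.shape != (len(self.frame), 2):
            raise ValueError("centroid must be (n_frames, 2)")
        if self.head.shape != self.centroid.shape:
            raise ValueError("head must match centroid shape")
        if self.valid is None:
            self.valid = (np.isfinite(self.centroid).all(axis=1)
                          & np.isfinite(self.head).all(axis=1))
        else:
            self.valid = np.asarray(self.valid, bool)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class PolarTrack:
    """Polar-coordinate view of a planar track: radius, angle, heading."""

    r: np.ndarray
    theta: np.ndarray
    psi: np.ndarray
    fps: float
    valid: np.ndarray
    theta_unwrapped: np.ndarray | None = None


@dataclass
class AlignmentSeries:
    """Pairwise alignment angles A01/A10 in [0, pi] with smoothed variants."""

    t: np.ndarray
    A01: np.ndarray
    A10: np.ndarray
    A01_smooth: np.ndarray | None = None
    A10_smooth: np.ndarray | None = None
    window_s: float | None = None


def wrapped_diff(theta: np.ndarray) -> np.ndarray:
    """Consecutive angular increments wrapped into (-pi, pi].

    Raw differencing of wrapped angles would corrupt the drift estimate
    at every lap boundary.
    """
    d = np.diff(np.asarray(theta, float))
    return np.angle(np.exp(1j * d))


def _wrap_dist(a: np.ndarray, b) -> np.ndarray:
    """Wrapped angular distance |a - b| in [0, pi]."""
    return np.abs(np.angle(np.exp(1j * (np.asarray(a) - b))))


def to_polar(track: PlanarTrack, center=(0.0, 0.0)) -> PolarTrack:
    """Polar coordinates of the centroid about ``center``, plus heading.

    theta is atan2 wrapped to [0, 2pi); ``theta_unwrapped`` accumulates
    laps continuously across valid frames.  A centroid exactly at the
    center has no defined angle and that frame is masked.
    """
    center = np.asarray(center, float)
    if not np.all(np.isfinite(center)):
        raise ValueError("center must be finite")
    rel = track.centroid - center
    r = np.hypot(rel[:, 0], rel[:, 1])
    valid = track.valid & (r > 0)
    theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), TWO_PI)
    theta = np.where(valid, theta, np.nan)

    unwrapped = np.full(len(theta), np.nan)
    iv = np.flatnonzero(valid)
    if iv.size:
        unwrapped[iv] = np.unwrap(theta[iv])

    psi = heading(track)
    return PolarTrack(r=np.where(valid, r, np.nan), theta=theta, psi=psi,
                      fps=track.fps, valid=valid, theta_unwrapped=unwrapped)


def heading(track: PlanarTrack) -> np.ndarray:
    """Heading psi: angle of the centroid-to-head vector, in [0, 2pi).

    Frames where head and centroid coincide (or are missing) yield NaN.
    """
    d = track.head - track.centroid
    ok = track.valid & (np.hypot(d[:, 0], d[:, 1]) > 0)
    psi = np.mod(np.arctan2(d[:, 1], d[:, 0]), TWO_PI)
    return np.where(ok, psi, np.nan)


def fix_heading_flips(psi: np.ndarray,
                      threshold: float = FLIP_THRESHOLD) -> np.ndarray:
    """Repair near-pi heading jumps caused by head/tail misidentification.

    Scanning forward over valid entries, whenever the wrapped angular jump
    from the previous (already corrected) heading exceeds ``threshold``
    the new value is overwritten with that previous heading.  Corrections
    cascade, which makes the pass idempotent and stable under runs of
    consecutive flipped frames.  NaN entries are skipped and preserved.
    """
    if not 0 < threshold <= np.pi:
        raise ValueError(f"threshold must lie in (0, pi], got {threshold}")
    psi = np.asarray(psi, float).copy()
    prev = None
    for i in range(len(psi)):
        if not np.isfinite(psi[i]):
            continue
        if prev is not None and _wrap_dist(psi[i], psi[prev]) > threshold:
            psi[i] = psi[prev]
        prev = i
    return psi


def alignment(track_i: PlanarTrack, track_j: PlanarTrack,
              psi_i: np.ndarray | None = None) -> np.ndarray:
    """Alignment angle A_ij in [0, pi] of animal i relative to animal j.

    The unsigned angle between i's heading vector and the vector from
    i's centroid to j's centroid: near 0 when i swims directly towards j
    (following), near pi when i swims directly away (leading).  A repaired
    heading series may be supplied via ``psi_i``; frames with coincident
    centroids or missing data are NaN.
    """
    if len(track_i) != len(track_j):
        raise ValueError("tracks must cover the same frames")
    if psi_i is None:
        psi_i = heading(track_i)
    sep = track_j.centroid - track_i.centroid
    dist = np.hypot(sep[:, 0], sep[:, 1])
    ok = track_i.valid & track_j.valid & (dist > 0) & np.isfinite(psi_i)
    ang = np.arctan2(sep[:, 1], sep[:, 0])
    return np.where(ok, _wrap_dist(psi_i, ang), np.nan)


def rolling_mean(series: np.ndarray, window_s: float = 15.0,
                 fps: float = 40.0, centered: bool = True) -> np.ndarray:
    """Mask-aware centred moving average over a fixed-duration window.

    NaN entries are excluded from both numerator and denominator; edge
    windows average over whatever frames are available.  Points whose
    window holds no valid frame stay NaN.
    """
    if window_s <= 0:
        raise ValueError(f"window must be > 0, got {window_s}")
    frames = max(1, int(round(window_s * fps)))
    s = pd.Series(np.asarray(series, float))
    return s.rolling(frames, center=centered, min_periods=1).mean().to_numpy()


def estimate_drift_noise(theta0: np.ndarray, theta1: np.ndarray,
                         valid0: np.ndarray | None = None,
                         valid1: np.ndarray | None = None,
                         ) -> tuple[float, float]:
    """Estimate (Omega, sigma) from the pooled wrapped angular increments.

    Omega is the mean and sigma the standard deviation of the per-frame
    wrapped increments Delta-theta, pooled over both animals across the
    whole series.  Increments spanning a masked frame are dropped.

    Note: on output of the leader-follower dyad model this pooled sigma
    converges to sqrt(2) x the model noise (the follower's increments
    carry variance 3 sigma^2 by construction); on independent
    drift-diffusions it is a consistent estimator.
    """
    diffs = []
    for th, ok in ((theta0, valid0), (theta1, valid1)):
        th = np.asarray(th, float)
        ok = np.isfinite(th) if ok is None else (np.asarray(ok, bool)
                                                 & np.isfinite(th))
        d = wrapped_diff(th)
        both = ok[:-1] & ok[1:]
        diffs.append(d[both])
    pooled = np.concatenate(diffs)
    if pooled.size < 2:
        raise ValueError("need at least two valid consecutive frames")
    return float(np.mean(pooled)), float(np.std(pooled, ddof=1))


def alignment_series(track0: PlanarTrack, track1: PlanarTrack,
                     window_s: float = 15.0,
                     psi0: np.ndarray | None = None,
                     psi1: np.ndarray | None = None) -> AlignmentSeries:
    """Convenience wrapper: both alignment angles with rolling smoothing."""
    A01 = alignment(track0, track1, psi_i=psi0)
    A10 = alignment(track1, track0, psi_i=psi1)
    fps = track0.fps
    return AlignmentSeries(
        t=np.asarray(track0.frame) / fps, A01=A01, A10=A10,
        A01_smooth=rolling_mean(A01, window_s, fps),
        A10_smooth=rolling_mean(A10, window_s, fps),
        window_s=window_s)
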