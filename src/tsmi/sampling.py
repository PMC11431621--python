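"""Decorrelated time-point selection and jackknife subset machinery.

Statistics computed from a single trajectory require sample pairs far
enough apart in time that their mutual correlations have decayed.  The
scheme implemented here tiles the series into non-overlapping intervals
of length ``W`` and draws one time index per interval from a symmetric
triangular density, so consecutive draws are separated by ``W`` steps on
average while still randomising their exact positions.  Repeating the
draw produces replicate datasets of full size, unlike jackknifing, which
must shrink the data to resample it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WindowPlan",
    "plan_windows",
    "triangular_sample",
    "windowed_indices",
    "jackknife_subsets",
]


@dataclass(frozen=True)
class WindowPlan:
    """Tiling of ``[0, n_steps)`` into consecutive length-``W`` intervals.

    ``intervals`` holds half-open ``[start, stop)`` pairs; a trailing
    partial interval is discarded so every interval has exact length W.
    """

    W: int
    intervals: list[tuple[int, int]]
    n_resamples: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.W < 1:
            raise ValueError(f"window length must be >= 1, got {self.W}")
        for lo, hi in self.intervals:
            if hi - lo != self.W:
                raise ValueError("every interval must have length W")


def plan_windows(n_steps: int, W: int, n_resamples: int = 10,
                 seed: int | None = None) -> WindowPlan:
    """Tile ``[0, n_steps)`` into ``n_steps // W`` windows of length W."""
    if W < 1:
        raise ValueError(f"window length must be >= 1, got {W}")
    if n_steps < W:
        raise ValueError(f"series of length {n_steps} shorter than window {W}")
    n_win = n_steps // W
    intervals = [(i * W, (i + 1) * W) for i in range(n_win)]
    return WindowPlan(W=W, intervals=intervals, n_resamples=n_resamples, seed=seed)


def triangular_sample(interval: tuple[int, int], rng: np.random.Generator) -> int:
    """Draw one integer time index from a symmetric triangular density.

    The density rises linearly from 0 at the interval endpoints to 2/W at
    the midpoint, so indices near the middle of the interval are strongly
    preferred.  The continuous draw is rounded to the nearest integer
    index inside ``[lo, hi)``.
    """
    lo, hi = interval
    if hi - lo < 1:
        raise ValueError(f"empty interval {interval}")
    x = rng.triangular(lo, (lo + hi) / 2.0, hi)
    return int(min(hi - 1, max(lo, round(x))))


def windowed_indices(n_steps: int, W: int, rng: np.random.Generator) -> np.ndarray:
    """One triangular draw per complete length-W interval of ``[0, n_steps)``.

    Returns a strictly increasing integer array with one index per
    interval; a trailing partial interval is discarded.  For W=1 every
    index is selected (the degenerate, fully correlated case).
    """
    plan = plan_windows(n_steps, W)
    return np.array([triangular_sample(iv, rng) for iv in plan.intervals],
                    dtype=np.intp)


def jackknife_subsets(N: int, n_subsets: int, subset_size: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Independently drawn random subsets of ``{0..N-1}`` without replacement.

    Each subset contains ``subset_size`` unique indices; different subsets
    are drawn independently of one another and may overlap.
    """
    if subset_size > N:
        raise ValueError(
            f"subset_size {subset_size} exceeds population size {N}")
    if n_subsets < 1:
        raise ValueError("need at least one subset")
    return [rng.choice(N, size=subset_size, replace=False)
            for _ in range(n_subsets)]
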