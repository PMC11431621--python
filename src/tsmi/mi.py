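"""KSG k-nearest-neighbour mutual information and time-separated MI curves.

The estimator is the Kraskov-Stoegbauer-Grassberger variant I(1):

    I_hat = psi(k) + psi(N) - < psi(n_x + 1) + psi(n_y + 1) >,

where the k-th neighbour distance of each point is measured with the
max-norm in the joint space and n_x, n_y count the strictly closer
marginal neighbours.  Estimates are returned in nats and may be slightly
negative for weakly dependent samples; they are never clipped.

Time-separated curves pair one agent's angle at time t with the other's
at t - tau and scan tau.  For a leader-follower dyad the curve peaks at
tau = T (the follower's reaction delay); by convention tau > 0 presumes
agent 0 leads, and the tau < 0 branch carries the index-swapped pairing.
Curves can be built from an ensemble of replicate simulations (with
jackknife subsets supplying standard errors) or from a single long
trajectory via triangular window sampling (see :mod:`tsmi.sampling`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from .sampling import jackknife_subsets, windowed_indices

__all__ = [
    "SamplePairs",
    "MICurve",
    "ksg_mi",
    "mi_curve_ensemble",
    "mi_curve_single",
    "mi_curve_ensemble_groups",
    "mi_curve_segments",
    "mirror_combine",
    "write_curve_csv",
    "read_curve_csv",
    "nats_to_bits",
]

LN2 = float(np.log(2.0))


def nats_to_bits(value):
    """Display conversion; all internal quantities are in nats."""
    return np.asarray(value) / LN2


@dataclass(frozen=True)
class SamplePairs:
    """Equal-length paired samples (x_i, y_i) at a fixed time separation.

    ``x`` and ``y`` may be 1-d scalar samples or (n, d) embedded vectors
    (d=2 for the chord embedding of circular data).
    """

    x: np.ndarray
    y: np.ndarray
    tau: float = 0.0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape[0] != y.shape[0]:
            raise ValueError("x and y must have equal sample counts")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.shape[0]


def _as_2d(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def ksg_mi(pairs: SamplePairs, k: int = 4, jitter_seed: int = 0) -> float:
    """KSG variant I(1) mutual information of paired samples, in nats.

    A deterministic, seeded jitter of magnitude 1e-10 x data scale breaks
    exact ties, under which k-NN neighbour counts are undefined.  Small
    negative values are legitimate small-sample output and are returned
    unclipped.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    x, y = _as_2d(pairs.x).copy(), _as_2d(pairs.y).copy()
    n = x.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} samples, got {n}")

    rng = np.random.default_rng(jitter_seed)
    for a in (x, y):
        scale = np.max(np.std(a, axis=0))
        a += 1e-10 * (scale if scale > 0 else 1.0) * rng.standard_normal(a.shape)

    joint = np.hstack([x, y])
    eps = cKDTree(joint).query(joint, k=[k + 1], p=np.inf)[0].ravel()
    # Strictly-closer marginal counts: shrink the radius below eps.
    r = np.nextafter(eps, 0.0)
    nx = cKDTree(x).query_ball_point(x, r, p=np.inf, return_length=True) - 1
    ny = cKDTree(y).query_ball_point(y, r, p=np.inf, return_length=True) - 1
    return float(digamma(k) + digamma(n)
                 - np.mean(digamma(nx + 1) + digamma(ny + 1)))


@dataclass
class MICurve:
    """Mean time-separated MI on a tau grid, with jackknife standard errors.

    ``convention`` records which agent is presumed leader on tau > 0.
    """

    tau: np.ndarray
    mi_mean: np.ndarray
    mi_se: np.ndarray
    n_samples: np.ndarray
    convention: str = "agent 0 presumed leader on tau>0"

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.mi_mean = np.asarray(self.mi_mean, dtype=float)
        self.mi_se = np.asarray(self.mi_se, dtype=float)
        self.n_samples = np.asarray(self.n_samples)
        if not (len(self.tau) == len(self.mi_mean) == len(self.mi_se)
                == len(self.n_samples)):
            raise ValueError("all curve columns must have equal length")
        if np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau grid must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.mi_se < 0):
                raise ValueError("standard errors must be >= 0")

    def __len__(self) -> int:
        return len(self.tau)


def default_tau_grid(tau_max: float = 2.5, n_points: int = 101) -> np.ndarray:
    """Symmetric tau grid in seconds; 101 points gives 0.05 s spacing."""
    return np.linspace(-tau_max, tau_max, n_points)


def _tau_steps(tau_grid: np.ndarray, dt: float) -> np.ndarray:
    steps = np.rint(np.asarray(tau_grid) / dt).astype(int)
    return steps


def _series_pair(rep) -> tuple[np.ndarray, np.ndarray]:
    """Accept an AngularDyadTrack-like object or a plain (y, x) pair.

    Returns (series_y, series_x) where the curve pairs y(t) with x(t-tau);
    for a dyad, y is theta1 and x is theta0.  Passing ``(theta, theta)``
    yields the self-MI of a single walker.
    """
    if hasattr(rep, "theta0"):
        return rep.theta1, rep.theta0
    y, x = rep
    return np.asarray(y), np.asarray(x)


def _embed(a: np.ndarray, mode: str) -> np.ndarray:
    if mode == "chord":
        return np.column_stack([np.cos(a), np.sin(a)])
    return np.asarray(a)


def mi_curve_ensemble(replicates, tau_grid, t_star: int,
                      jack: tuple[int, int] = (10, 250), k: int = 4,
                      seed: int = 0, mode: str = "linear",
                      convention: str = "agent 0 presumed leader on tau>0",
                      ) -> MICurve:
    """Ensemble MI curve: pairs (theta1(t*), theta0(t* - tau)) across replicates.

    For each tau the replicate ensemble supplies one sample pair per
    replicate; ``jack = (n_subsets, subset_size)`` random subsets are drawn
    without replacement and the KSG estimate's mean and standard error
    across subsets are reported.  The same subset index sets are reused
    across the whole tau grid so curve-level noise is correlated in tau
    and the curve stays smooth.

    ``tau_grid`` is in seconds and is converted to whole steps with the
    replicates' dt; ``mode`` is "linear" (angles as points on the line,
    the default) or "chord" (embed theta -> (cos theta, sin theta)).
    """
    replicates = list(replicates)
    n_subsets, subset_size = jack
    N = len(replicates)
    if N < subset_size:
        raise ValueError(
            f"need at least subset_size={subset_size} replicates, got {N}")
    dt = getattr(replicates[0], "dt", 1.0)
    steps = _tau_steps(tau_grid, dt)
    n_len = len(_series_pair(replicates[0])[0])
    lo, hi = t_star - int(steps.max()), t_star - int(steps.min())
    if lo < 0 or hi >= n_len:
        raise ValueError(
            f"t_star={t_star} with tau range [{steps.min()}, {steps.max()}] "
            f"steps exceeds replicate length {n_len}")

    ys = np.array([_series_pair(r)[0][t_star] for r in replicates])
    xs_full = np.array([_series_pair(r)[1] for r in replicates])

    rng = np.random.default_rng(seed)
    subsets = jackknife_subsets(N, n_subsets, subset_size, rng)

    mean = np.empty(len(steps))
    se = np.empty(len(steps))
    for i, s in enumerate(steps):
        xs = xs_full[:, t_star - s]
        vals = [ksg_mi(SamplePairs(_embed(ys[idx], mode),
                                   _embed(xs[idx], mode)), k=k)
                for idx in subsets]
        mean[i] = np.mean(vals)
        se[i] = np.std(vals, ddof=1) / np.sqrt(n_subsets)
    return MICurve(tau=np.asarray(tau_grid, float), mi_mean=mean, mi_se=se,
                   n_samples=np.full(len(steps), subset_size),
                   convention=convention)


def mi_curve_single(theta0: np.ndarray, theta1: np.ndarray, tau_grid,
                    W: int, n_resamples: int = 10, k: int = 4,
                    dt: float = 1.0, seed: int = 0, mode: str = "linear",
                    valid0: np.ndarray | None = None,
                    valid1: np.ndarray | None = None,
                    min_pairs: int | None = None,
                    convention: str = "agent 0 presumed leader on tau>0",
                    ) -> MICurve:
    """Single-trajectory MI curve via triangular window sampling.

    Each resample draws one time point per length-``W`` interval of the
    theta1 series (see :func:`tsmi.sampling.windowed_indices`), pairs
    theta1(t) with theta0(t - tau), drops pairs whose shifted index falls
    outside the series or on an invalid frame, and runs the KSG estimator.
    The mean and standard error over ``n_resamples`` independent redraws
    are reported.  Grid points with fewer than ``min_pairs`` (default
    k + 2) valid pairs are emitted as NaN with a warning.
    """
    theta0 = np.asarray(theta0, float)
    theta1 = np.asarray(theta1, float)
    n = len(theta1)
    if len(theta0) != n:
        raise ValueError("theta0 and theta1 must have equal length")
    if min_pairs is None:
        min_pairs = k + 2
    steps = _tau_steps(tau_grid, dt)
    rng = np.random.default_rng(seed)
    draws = [windowed_indices(n, W, rng) for _ in range(n_resamples)]

    ok0 = np.ones(n, bool) if valid0 is None else np.asarray(valid0, bool)
    ok1 = np.ones(n, bool) if valid1 is None else np.asarray(valid1, bool)

    mean = np.empty(len(steps))
    se = np.empty(len(steps))
    n_samp = np.zeros(len(steps))
    for i, s in enumerate(steps):
        vals, counts = [], []
        for idx in draws:
            shifted = idx - s
            keep = (shifted >= 0) & (shifted < n)
            ii, jj = idx[keep], shifted[keep]
            keep2 = ok1[ii] & ok0[jj]
            ii, jj = ii[keep2], jj[keep2]
            if len(ii) < max(min_pairs, k + 1):
                continue
            vals.append(ksg_mi(SamplePairs(_embed(theta1[ii], mode),
                                           _embed(theta0[jj], mode)), k=k))
            counts.append(len(ii))
        if not vals:
            warnings.warn(
                f"tau={tau_grid[i]:.4g}: fewer than {min_pairs} valid pairs "
                "in every resample; grid point emitted as NaN", stacklevel=2)
            mean[i], se[i] = np.nan, 0.0
            continue
        mean[i] = np.mean(vals)
        se[i] = (np.std(vals, ddof=1) / np.sqrt(len(vals))
                 if len(vals) > 1 else 0.0)
        n_samp[i] = np.mean(counts)
    return MICurve(tau=np.asarray(tau_grid, float), mi_mean=mean, mi_se=se,
                   n_samples=n_samp, convention=convention)


def mi_curve_ensemble_groups(groups, tau_grid, t_star: int, k: int = 4,
                             mode: str = "linear",
                             convention: str = "agent 0 presumed leader on tau>0",
                             ) -> MICurve:
    """Ensemble MI curve with errors taken across independent ensembles.

    ``groups`` is a list of independent replicate ensembles; each yields
    one full-ensemble KSG estimate per tau, and the mean and standard
    error across groups are reported.  Unlike the overlapping jackknife
    subsets of :func:`mi_curve_ensemble`, group estimates share no data,
    so the quoted errors include the ensemble-level sampling fluctuation
    and are suitable for curve-to-curve comparisons.
    """
    groups = [list(g) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two independent groups")
    dt = getattr(groups[0][0], "dt", 1.0)
    steps = _tau_steps(tau_grid, dt)
    est = np.empty((len(groups), len(steps)))
    for gi, reps in enumerate(groups):
        ys = np.array([_series_pair(r)[0][t_star] for r in reps])
        xs = np.array([_series_pair(r)[1] for r in reps])
        for j, s in enumerate(steps):
            est[gi, j] = ksg_mi(SamplePairs(_embed(ys, mode),
                                            _embed(xs[:, t_star - s], mode)),
                                k=k)
    return MICurve(tau=np.asarray(tau_grid, float), mi_mean=est.mean(axis=0),
                   mi_se=est.std(axis=0, ddof=1) / np.sqrt(len(groups)),
                   n_samples=np.full(len(steps), len(groups[0])),
                   convention=convention)


def mi_curve_segments(theta0: np.ndarray, theta1: np.ndarray, tau_grid,
                      W: int, n_segments: int = 10, k: int = 4,
                      dt: float = 1.0, seed: int = 0, mode: str = "linear",
                      convention: str = "agent 0 presumed leader on tau>0",
                      ) -> MICurve:
    """Single-trajectory MI curve with errors taken across disjoint segments.

    The series is split into ``n_segments`` consecutive equal blocks; each
    block contributes one triangular-windowed KSG estimate per tau, and
    the mean and standard error across blocks are reported.  Because the
    blocks share no data, the quoted errors include the trajectory-level
    realisation noise that the within-trajectory resampling of
    :func:`mi_curve_single` cannot see.
    """
    theta0 = np.asarray(theta0, float)
    theta1 = np.asarray(theta1, float)
    n = len(theta1) // n_segments
    if n < W:
        raise ValueError("segments shorter than the window length")
    steps = _tau_steps(tau_grid, dt)
    rng = np.random.default_rng(seed)
    est = np.empty((n_segments, len(steps)))
    for g in range(n_segments):
        lo = g * n
        idx = windowed_indices(n, W, rng) + lo
        for j, s in enumerate(steps):
            sh = idx - s
            keep = (sh >= lo) & (sh < lo + n)
            if keep.sum() <= k:
                raise ValueError(
                    f"segment {g}: only {keep.sum()} pairs at tau index {j}")
            est[g, j] = ksg_mi(SamplePairs(_embed(theta1[idx[keep]], mode),
                                           _embed(theta0[sh[keep]], mode)),
                               k=k)
    return MICurve(tau=np.asarray(tau_grid, float), mi_mean=est.mean(axis=0),
                   mi_se=est.std(axis=0, ddof=1) / np.sqrt(n_segments),
                   n_samples=np.full(len(steps), n // W),
                   convention=convention)


def mirror_combine(curve_01: MICurve, curve_10: MICurve) -> MICurve:
    """Merge two positive-branch curves into one spanning [-tau_max, +tau_max].

    ``curve_01`` estimates MI(theta1(t); theta0(t - tau)) on tau >= 0
    (agent 0 presumed leader) and ``curve_10`` the index-swapped pairing
    on the same grid.  At steady state the swapped estimate at +tau equals
    the original at -tau, so it is placed on the negative branch; the two
    tau = 0 estimates target the same quantity and are averaged.
    """
    if not np.allclose(curve_01.tau, curve_10.tau):
        raise ValueError("curves must share the same tau grid")
    if np.any(curve_01.tau < 0):
        raise ValueError("input curves must be on a non-negative tau grid")
    t = curve_01.tau
    has0 = t[0] == 0.0
    if has0:
        m0 = 0.5 * (curve_01.mi_mean[0] + curve_10.mi_mean[0])
        s0 = 0.5 * np.hypot(curve_01.mi_se[0], curve_10.mi_se[0])
        tau = np.concatenate([-t[:0:-1], t])
        mean = np.concatenate([curve_10.mi_mean[:0:-1], [m0],
                               curve_01.mi_mean[1:]])
        se = np.concatenate([curve_10.mi_se[:0:-1], [s0], curve_01.mi_se[1:]])
        ns = np.concatenate([curve_10.n_samples[:0:-1],
                             [curve_01.n_samples[0]], curve_01.n_samples[1:]])
    else:
        tau = np.concatenate([-t[::-1], t])
        mean = np.concatenate([curve_10.mi_mean[::-1], curve_01.mi_mean])
        se = np.concatenate([curve_10.mi_se[::-1], curve_01.mi_se])
        ns = np.concatenate([curve_10.n_samples[::-1], curve_01.n_samples])
    return MICurve(tau=tau, mi_mean=mean, mi_se=se, n_samples=ns,
                   convention=curve_01.convention)


# ---------------------------------------------------------------------------
# curve I/O

def write_curve_csv(curve: MICurve, path) -> None:
    """CSV columns ``tau_s, mi_nats, se_nats, n``; convention in the header."""
    with open(path, "w") as fh:
        fh.write(f"# convention: {curve.convention}\n")
        pd.DataFrame({
            "tau_s": curve.tau, "mi_nats": curve.mi_mean,
            "se_nats": curve.mi_se, "n": curve.n_samples,
        }).to_csv(fh, index=False)


def read_curve_csv(path) -> MICurve:
    convention = "agent 0 presumed leader on tau>0"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# convention:"):
            convention = first.split(":", 1)[1].strip()
    df = pd.read_csv(path, comment="#")
    return MICurve(tau=df["tau_s"].to_numpy(), mi_mean=df["mi_nats"].to_numpy(),
                   mi_se=df["se_nats"].to_numpy(), n_samples=df["n"].to_numpy(),
                   convention=convention)
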