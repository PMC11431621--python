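"""Leader-follower dyad and random-walker simulators on the ring.

The dyad model places two point agents on a circle.  At every step the
current leader performs a drift-diffusion move,

    theta_L(t) = theta_L(t-1) + Omega + W_L(t),      W_L ~ N(0, sigma^2),

while the follower re-targets the leader's position ``T`` steps in the
past,

    theta_F(t) = theta_L(t-T) + W_F(t),              W_F ~ N(0, sigma^2),

both taken modulo 2*pi.  ``T`` is the follower's reaction delay in steps.
With probability ``alpha`` per step the leader/follower labels swap; both
agents' full histories are retained, so after a swap the new follower
reads the new leader's recorded past, which can produce a position jump
up to the current separation.  Before the first ``T`` steps the leader
history is clamped to its initial position (both agents are taken to be
immobile prior to initialisation).

Also provided: free and ring-confined Gaussian random walkers, and the
closed-form time-separated self mutual information of the free walker,
MI(x(t); x(t+tau)) = (1/2) ln(1 + t/tau), which serves as an analytic
oracle for the k-NN estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi

__all__ = [
    "LFConfig",
    "AngularDyadTrack",
    "WalkerTrack",
    "simulate_lf_dyad",
    "simulate_independent_pair",
    "simulate_walker",
    "analytic_free_walker_mi",
    "write_track_csv",
    "read_track_csv",
]

#: leader_id value meaning "no leader" (non-interacting pair).
NO_LEADER = -1


@dataclass(frozen=True)
class LFConfig:
    """Parameters of the ring leader-follower model.

    omega
        Angular drift of the leader, radians per step.
    sigma
        Standard deviation of the per-step Gaussian noise, radians.
    T
        Follower reaction delay, integer steps (>= 0).
    alpha
        Per-step probability that the leader/follower labels swap.
    n_steps
        Number of update steps; the emitted series have n_steps + 1 points.
    fps
        Steps per second (sets the physical timescale; 40 for the fish data).
    seed
        Seed for the generator; leader noise, follower noise, swap draws
        and the initial angle use four independent sub-streams, so e.g.
        changing ``alpha`` does not perturb the noise sequences.
    phi
        Initial angular offset theta0(0) - theta1(0), radians.
    theta0_init
        Initial angle of agent 0; drawn uniform on [0, 2pi) when None.
    """

    omega: float = 0.0067
    sigma: float = 0.0039
    T: int = 20
    alpha: float = 0.0
    n_steps: int = 24000
    fps: float = 40.0
    seed: int = 0
    phi: float = 0.5
    theta0_init: float | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.T < 0 or int(self.T) != self.T:
            raise ValueError(f"T must be a non-negative integer, got {self.T}")
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.n_steps <= self.T:
            raise ValueError(
                f"n_steps ({self.n_steps}) must exceed the delay T ({self.T})")

    @property
    def dt(self) -> float:
        return 1.0 / self.fps


@dataclass
class AngularDyadTrack:
    """Paired wrapped angular time series with per-step leadership labels.

    ``leader_id[t]`` is the index (0 or 1) of the agent acting as leader
    at step t, or ``NO_LEADER`` (-1) throughout for a non-interacting pair.
    """

    theta0: np.ndarray
    theta1: np.ndarray
    leader_id: np.ndarray
    dt: float
    t: np.ndarray
    config: LFConfig | None = None

    def __post_init__(self) -> None:
        n = len(self.theta0)
        if not (len(self.theta1) == len(self.leader_id) == len(self.t) == n):
            raise ValueError("all series must have equal length")
        for th in (self.theta0, self.theta1):
            if np.any((th < 0) | (th >= TWO_PI)):
                raise ValueError("angles must lie in [0, 2*pi)")

    def __len__(self) -> int:
        return len(self.theta0)

    @property
    def fps(self) -> float:
        return 1.0 / self.dt


@dataclass
class WalkerTrack:
    """Gaussian random walker, free on the line or confined to a ring.

    Exactly one of ``x`` (free) / ``theta`` (ring, wrapped to [0, 2pi))
    is present, matching ``confined``.
    """

    confined: bool
    sigma2: float
    dt: float
    x: np.ndarray | None = None
    theta: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.confined and (self.theta is None or self.x is not None):
            raise ValueError("confined walker must carry theta only")
        if not self.confined and (self.x is None or self.theta is not None):
            raise ValueError("free walker must carry x only")

    @property
    def series(self) -> np.ndarray:
        return self.theta if self.confined else self.x

    def __len__(self) -> int:
        return len(self.series)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_lf_dyad(config: LFConfig) -> AngularDyadTrack:
    """Simulate the ring leader-follower dyad.

    Agent 0 starts as leader.  Label swaps are independent Bernoulli(alpha)
    events per step; between swaps the dynamics are advanced segment-wise
    with vectorised arithmetic, so the cost is O(n_steps).
    """
    c = config
    lead_rng, fol_rng, swap_rng, init_rng = _streams(c.seed, 4)
    n = c.n_steps

    th = np.empty((2, n + 1))
    th0 = (init_rng.uniform(0.0, TWO_PI) if c.theta0_init is None
           else float(c.theta0_init) % TWO_PI)
    th[0, 0] = th0
    th[1, 0] = (th0 - c.phi) % TWO_PI

    # Pre-drawn noise: the "leader" stream drives whichever agent currently
    # leads, so the realised noise sequence is independent of alpha.
    lead_noise = lead_rng.normal(0.0, c.sigma, size=n)
    fol_noise = fol_rng.normal(0.0, c.sigma, size=n)
    swaps = swap_rng.random(n) < c.alpha

    leader_id = np.empty(n + 1, dtype=np.int8)
    leader_id[0] = 0
    leader_id[1:] = np.cumsum(swaps) % 2

    # Segment boundaries: steps 1..n split wherever the label changes.
    change = np.flatnonzero(leader_id[1:] != leader_id[:-1]) + 1
    starts = np.concatenate(([1], change))
    stops = np.concatenate((change, [n + 1]))
    for s, e in zip(starts, stops):
        if s >= e:
            continue
        L = int(leader_id[s])
        F = 1 - L
        inc = c.omega + lead_noise[s - 1:e - 1]
        th[L, s:e] = (th[L, s - 1] + np.cumsum(inc)) % TWO_PI
        src = np.maximum(np.arange(s, e) - c.T, 0)
        th[F, s:e] = (th[L, src] + fol_noise[s - 1:e - 1]) % TWO_PI

    return AngularDyadTrack(theta0=th[0], theta1=th[1], leader_id=leader_id,
                            dt=c.dt, t=np.arange(n + 1), config=c)


def simulate_independent_pair(config: LFConfig) -> AngularDyadTrack:
    """Two non-interacting drift-diffusions on the ring.

    Both agents obey the leader dynamics; there is no follower and
    ``leader_id`` is the sentinel ``NO_LEADER`` (-1) at every step.
    The initial offset ``phi`` is applied exactly as in the dyad.
    """
    c = config
    rng0, rng1, _, init_rng = _streams(c.seed, 4)
    n = c.n_steps
    th0 = (init_rng.uniform(0.0, TWO_PI) if c.theta0_init is None
           else float(c.theta0_init) % TWO_PI)

    inc0 = c.omega + rng0.normal(0.0, c.sigma, size=n)
    inc1 = c.omega + rng1.normal(0.0, c.sigma, size=n)
    theta0 = np.concatenate(([th0], th0 + np.cumsum(inc0))) % TWO_PI
    theta1 = np.concatenate(([0.0], np.cumsum(inc1)))
    theta1 = (theta1 + (th0 - c.phi)) % TWO_PI

    leader_id = np.full(n + 1, NO_LEADER, dtype=np.int8)
    return AngularDyadTrack(theta0=theta0, theta1=theta1, leader_id=leader_id,
                            dt=c.dt, t=np.arange(n + 1), config=c)


def simulate_walker(n_steps: int, sigma2: float, confined: bool,
                    seed: int = 0, fps: float = 1.0,
                    theta_init: float | None = None) -> WalkerTrack:
    """Gaussian random walker; free on the line or wrapped onto the ring.

    The free walker starts at x=0; the ring walker starts uniform on
    [0, 2pi) unless ``theta_init`` is given.  ``sigma2`` is the variance
    of the per-step increments.
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    rng = np.random.default_rng(seed)
    if confined:
        start = rng.uniform(0.0, TWO_PI) if theta_init is None else theta_init
    else:
        start = 0.0
    steps = rng.normal(0.0, np.sqrt(sigma2), size=n_steps)
    path = np.concatenate(([start], start + np.cumsum(steps)))
    if confined:
        return WalkerTrack(confined=True, sigma2=sigma2, dt=1.0 / fps,
                           theta=path % TWO_PI)
    return WalkerTrack(confined=False, sigma2=sigma2, dt=1.0 / fps, x=path)


def analytic_free_walker_mi(t: float, tau: float) -> float:
    """Closed-form self MI of the free Gaussian walker, in nats.

    MI(x(t); x(t+tau)) = (1/2) ln(1 + t/tau): for fixed separation tau the
    information grows logarithmically in t because the walker's positional
    variance grows linearly while the increment variance between the two
    times stays fixed.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return 0.5 * float(np.log1p(t / tau))


# ---------------------------------------------------------------------------
# track I/O

def write_track_csv(track: AngularDyadTrack, path) -> None:
    """Write ``t, theta0, theta1, leader_id`` with dt/config header comments."""
    with open(path, "w") as fh:
        fh.write(f"# dt={track.dt!r}\n")
        if track.config is not None:
            c = track.config
            items = (f"omega={c.omega!r} sigma={c.sigma!r} T={c.T} "
                     f"alpha={c.alpha!r} n_steps={c.n_steps} fps={c.fps!r} "
                     f"seed={c.seed} phi={c.phi!r}")
            fh.write(f"# config: {items}\n")
        pd.DataFrame({
            "t": track.t, "theta0": track.theta0, "theta1": track.theta1,
            "leader_id": track.leader_id,
        }).to_csv(fh, index=False)


def read_track_csv(path) -> AngularDyadTrack:
    """Read a track written by :func:`write_track_csv`."""
    dt = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# dt="):
                dt = float(line.split("=", 1)[1])
    if dt is None:
        raise ValueError(f"{path}: missing '# dt=' header")
    df = pd.read_csv(path, comment="#")
    return AngularDyadTrack(
        theta0=df["theta0"].to_numpy(), theta1=df["theta1"].to_numpy(),
        leader_id=df["leader_id"].to_numpy(np.int8), dt=dt,
        t=df["t"].to_numpy(np.intp))
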