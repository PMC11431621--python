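"""Render angular dyad simulations into TRex-like planar tracks.

The dyad model lives on a one-dimensional ring; real tracking data are
per-frame planar centroid and head positions in an annular tank.  This
module bridges the two so the preprocessing pipeline and the full
analysis can be exercised end to end without any recorded video: each
agent's angle is placed on a circle of mean radius ``r_mean`` with
smooth AR(1) radial jitter, the head is offset half a body length along
the instantaneous direction of angular motion, and the two dominant
tracking artefacts are injected on demand — head/tail identification
flips (the head vector negated with probability ``p_flip`` per frame)
and missing frames (blanked with probability ``p_miss``).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import numpy as np

from .prep import PlanarTrack, wrapped_diff
from .simulate import AngularDyadTrack

__all__ = ["RenderConfig", "render_planar", "write_trex_csv", "read_trex_csv"]


@dataclass(frozen=True)
class RenderConfig:
    """Geometry and artefact rates for planar rendering.

    Distances in cm; tank defaults follow the annular arena used for the
    shiner recordings (outer/inner diameters 125.1 / 26.2 cm).  The AR(1)
    coefficient keeps the radial jitter smooth frame to frame — real fish
    do not teleport radially.
    """

    r_mean: float = 30.0
    r_jitter_sd: float = 1.0
    body_length: float = 5.0
    p_flip: float = 0.0
    p_miss: float = 0.0
    fps: float = 40.0
    seed: int = 0
    tank_outer_diameter: float = 125.1
    tank_inner_diameter: float = 26.2
    ar1_coeff: float = 0.95

    def __post_init__(self) -> None:
        for name in ("p_flip", "p_miss"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        inner_r = self.tank_inner_diameter / 2.0
        outer_r = self.tank_outer_diameter / 2.0
        if not inner_r < self.r_mean < outer_r:
            raise ValueError(
                f"r_mean={self.r_mean} outside annulus ({inner_r}, {outer_r})")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ValueError("ar1_coeff must lie in [0, 1)")
        if (self.r_mean - 3 * self.r_jitter_sd <= inner_r
                or self.r_mean + 3 * self.r_jitter_sd >= outer_r):
            warnings.warn("radial jitter brings agents within 3 sd of a tank "
                          "wall; radii will be clipped", stacklevel=2)

    @property
    def inner_radius(self) -> float:
        return self.tank_inner_diameter / 2.0

    @property
    def outer_radius(self) -> float:
        return self.tank_outer_diameter / 2.0


def _motion_sign(theta: np.ndarray) -> np.ndarray:
    """Sign of the instantaneous angular motion, carried over zero steps."""
    d = wrapped_diff(theta)
    s = np.sign(d)
    s = np.concatenate([s, s[-1:]])  # last frame keeps its incoming direction
    # fill zeros (no motion) with the previous non-zero direction
    prev = 1.0
    for i in range(len(s)):
        if s[i] == 0.0:
            s[i] = prev
        else:
            prev = s[i]
    return s


def render_planar(dyad: AngularDyadTrack, cfg: RenderConfig,
                  ) -> tuple[PlanarTrack, PlanarTrack]:
    """Render both agents of a dyad into planar centroid/head tracks."""
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(cfg.seed).spawn(2)]
    tracks = []
    phi = cfg.ar1_coeff
    for theta, rng in zip((dyad.theta0, dyad.theta1), rngs):
        n = len(theta)
        # stationary AR(1) jitter with marginal sd = r_jitter_sd
        jitter = np.zeros(n)
        if cfg.r_jitter_sd > 0:
            innov = rng.normal(0.0, cfg.r_jitter_sd * np.sqrt(1 - phi ** 2),
                               size=n)
            jitter[0] = rng.normal(0.0, cfg.r_jitter_sd)
            for i in range(1, n):
                jitter[i] = phi * jitter[i - 1] + innov[i]
        r = np.clip(cfg.r_mean + jitter, cfg.inner_radius, cfg.outer_radius)

        centroid = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        sign = _motion_sign(theta)
        tangent = np.column_stack([-np.sin(theta), np.cos(theta)]) * sign[:, None]
        head_vec = (cfg.body_length / 2.0) * tangent
        if cfg.p_flip > 0:
            flip = rng.random(n) < cfg.p_flip
            head_vec[flip] *= -1.0
        head = centroid + head_vec

        valid = np.ones(n, bool)
        if cfg.p_miss > 0:
            valid &= rng.random(n) >= cfg.p_miss
            centroid[~valid] = np.nan
            head[~valid] = np.nan
        tracks.append(PlanarTrack(frame=np.arange(n), centroid=centroid,
                                  head=head, fps=cfg.fps, valid=valid))
    return tracks[0], tracks[1]


# ---------------------------------------------------------------------------
# TRex-like CSV dialect: frame, x0, y0, hx0, hy0, x1, y1, hx1, hy1 (cm);
# blank cells mark missing data; fps rides in a '# fps=' header comment.

_COLUMNS = ["frame", "x0", "y0", "hx0", "hy0", "x1", "y1", "hx1", "hy1"]


def write_trex_csv(tracks: tuple[PlanarTrack, PlanarTrack], path) -> None:
    """Write a pair of planar tracks; masked frames become blank cells."""
    t0, t1 = tracks
    if len(t0) != len(t1):
        raise ValueError("tracks must cover the same frames")

    def cells(tr: PlanarTrack, i: int) -> list[str]:
        if not tr.valid[i]:
            return [""] * 4
        return [f"{tr.centroid[i, 0]:.6f}", f"{tr.centroid[i, 1]:.6f}",
                f"{tr.head[i, 0]:.6f}", f"{tr.head[i, 1]:.6f}"]

    with open(path, "w", newline="") as fh:
        fh.write(f"# fps={t0.fps!r}\n")
        w = csv.writer(fh)
        w.writerow(_COLUMNS)
        for i in range(len(t0)):
            w.writerow([int(t0.frame[i])] + cells(t0, i) + cells(t1, i))


def read_trex_csv(path, fps: float | None = None,
                  ) -> tuple[PlanarTrack, PlanarTrack]:
    """Read the dialect written by :func:`write_trex_csv`.

    ``fps`` read from the '# fps=' header comment unless overridden;
    defaults to 40 when absent.  Malformed rows raise with their line
    number.
    """
    header_fps = None
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if row[0].startswith("#"):
                text = ",".join(row)
                if "fps=" in text:
                    header_fps = float(text.split("fps=", 1)[1])
                continue
            if row == _COLUMNS:
                continue
            if len(row) != len(_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(_COLUMNS)} fields, "
                    f"got {len(row)}")
            try:
                frame = int(row[0])
                vals = [float(c) if c.strip() else np.nan for c in row[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            rows.append([frame] + vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows, float)
    fps_val = fps if fps is not None else (header_fps or 40.0)
    frames = arr[:, 0].astype(np.intp)
    t0 = PlanarTrack(frame=frames, centroid=arr[:, 1:3], head=arr[:, 3:5],
                     fps=fps_val)
    t1 = PlanarTrack(frame=frames, centroid=arr[:, 5:7], head=arr[:, 7:9],
                     fps=fps_val)
    return t0, t1
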