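"""Rodent-like random-foraging trajectories at 50 Hz.

Speed is drawn each step from a Rayleigh distribution matched to the
configured mean running speed; heading performs a random walk driven by a
zero-mean Gaussian angular velocity.  Near walls the agent decelerates and
turns toward the interior, which reproduces the wall-following bouts and
thorough but inhomogeneous coverage characteristic of foraging rodents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import Environment, ray_segment_distances


class ConfinementError(RuntimeError):
    """No admissible step found after the retry budget (stuck agent)."""


@dataclass(frozen=True)
class MotionParams:
    dt: float = 0.02               # s; 50 Hz sampling
    mean_speed: float = 0.13       # m/s
    turn_sigma: float = 5.9        # rad/s SD of angular velocity
    wall_margin: float = 0.03      # m; look-ahead clearance triggering avoidance
    wall_turn: tuple[float, float] = (math.pi / 4, math.pi / 2)  # rad, turn range
    max_retries: int = 50

    def __post_init__(self) -> None:
        if min(self.dt, self.mean_speed, self.turn_sigma, self.wall_margin) <= 0:
            raise ValueError("all motion scales must be positive")

    @property
    def rayleigh_scale(self) -> float:
        # Rayleigh mean = scale * sqrt(pi/2)
        return self.mean_speed / math.sqrt(math.pi / 2)


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped 50 Hz path: t (s), x/y (m), heading (rad)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray

    def __len__(self) -> int:
        return self.t.size

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, "x": self.x, "y": self.y, "heading": self.heading})

    @classmethod
    def from_dataframe(cls, df) -> "Trajectory":
        return cls(
            t=df["t"].to_numpy(float),
            x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float),
            heading=df["heading"].to_numpy(float),
        )


class _RayCaster:
    """Single-ray distance queries vectorised over all wall segments."""

    def __init__(self, segments: np.ndarray) -> None:
        self.ax = segments[:, 0, 0]
        self.ay = segments[:, 0, 1]
        self.ex = segments[:, 1, 0] - self.ax
        self.ey = segments[:, 1, 1] - self.ay

    def dist(self, x: float, y: float, theta: float) -> float:
        dx, dy = math.cos(theta), math.sin(theta)
        denom = dx * self.ey - dy * self.ex
        with np.errstate(divide="ignore", invalid="ignore"):
            t = ((self.ax - x) * self.ey - (self.ay - y) * self.ex) / denom
            u = ((self.ax - x) * dy - (self.ay - y) * dx) / denom
        hit = (np.abs(denom) > 1e-14) & (t > 1e-12) & (u >= -1e-12) & (u <= 1 + 1e-12)
        return float(t[hit].min()) if hit.any() else math.inf


def _ray(env_segments: np.ndarray | _RayCaster, x: float, y: float, theta: float) -> float:
    if isinstance(env_segments, _RayCaster):
        return env_segments.dist(x, y, theta)
    d = ray_segment_distances(np.array([[x, y]]), np.array([theta]), env_segments)
    return float(d[0, 0])


def motion_step(
    state: tuple[float, float, float, float],
    env: Environment,
    params: MotionParams,
    rng: np.random.Generator,
    _caster: _RayCaster | None = None,
) -> tuple[float, float, float, float]:
    """Advance one 20 ms step: returns (x, y, heading, speed).

    Speed is resampled from the Rayleigh distribution; heading gets a
    Gaussian angular-velocity increment.  If the look-ahead point along the
    new heading comes within wall_margin of any wall or barrier, the agent
    turns away from the wall by a uniform draw from wall_turn and halves its
    speed.  Steps that would exit the arena or cross a barrier are rejected
    and re-drawn (bounded retries).
    """
    x, y, heading, _ = state
    segs = _caster if _caster is not None else _RayCaster(env.segments)
    for attempt in range(params.max_retries):
        speed = rng.rayleigh(params.rayleigh_scale)
        heading = heading + rng.normal(0.0, params.turn_sigma * params.dt)
        clearance = _ray(segs, x, y, heading)
        if clearance < params.wall_margin + speed * params.dt:
            # turn away from the wall, toward whichever side is more open
            turn = rng.uniform(*params.wall_turn)
            left = _ray(segs, x, y, heading + math.pi / 2)
            right = _ray(segs, x, y, heading - math.pi / 2)
            heading = heading + (turn if left >= right else -turn)
            speed *= 0.5
            clearance = _ray(segs, x, y, heading)
        step = speed * params.dt
        if step < clearance:  # move stays inside and crosses nothing
            nx = x + step * math.cos(heading)
            ny = y + step * math.sin(heading)
            return nx, ny, heading % (2 * math.pi), speed
        # rejected: retry with a fresh draw (speed 0 step is always legal,
        # so in the worst case the agent pauses in place)
        if attempt == params.max_retries - 2:
            return x, y, heading % (2 * math.pi), 0.0
    raise ConfinementError("no admissible step found")


def simulate_trajectory(
    env: Environment,
    duration: float,
    params: MotionParams | None = None,
    *,
    seed: int | np.random.Generator = 0,
    start: tuple[float, float] | None = None,
) -> Trajectory:
    """Simulate ``duration`` seconds of foraging; duration/dt + 1 samples.

    Deterministic given the seed.  The start position defaults to a random
    interior bin center.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    params = params or MotionParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_steps = int(round(duration / params.dt))
    if start is None:
        mask = env.bin_mask()
        xs, ys = env.bin_centers()
        rows, cols = np.nonzero(mask)
        k = rng.integers(rows.size)
        start = (float(xs[cols[k]]), float(ys[rows[k]]))
    x = np.empty(n_steps + 1)
    y = np.empty(n_steps + 1)
    heading = np.empty(n_steps + 1)
    x[0], y[0] = start
    heading[0] = rng.uniform(0, 2 * math.pi)
    state = (x[0], y[0], heading[0], params.mean_speed)
    caster = _RayCaster(env.segments)
    for i in range(1, n_steps + 1):
        state = motion_step(state, env, params, rng, _caster=caster)
        x[i], y[i], heading[i] = state[0], state[1], state[2]
    t = np.arange(n_steps + 1) * params.dt
    return Trajectory(t=t, x=x, y=y, heading=heading)
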