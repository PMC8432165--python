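"""Standard discrete-state (grid-world) successor representation.

The comparison model discretises the arena into coarse spatial bins and
computes the SR of a uniform random walk over accessible bins in closed
form, M = (I - gamma P)^-1.  Place cells are columns of M reshaped onto the
bin grid; grid cells are eigenvectors of M thresholded at zero, with the
same map conventions as the feature-based model.  Because the states are
abstract bins, inserting a barrier without relearning leaves every map
unchanged — the limitation the feature-based model removes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cells import EigenMode, RateMap
from .geometry import Environment, segment_blocked

STATE_BIN_SIZE = 0.05


@dataclass(frozen=True)
class TabularSR:
    """Closed-form SR over accessible spatial bins."""

    M: np.ndarray                 # (n_states, n_states)
    gamma: float
    state_grid: np.ndarray        # (ny, nx) int map: state index or -1
    bin_size: float
    env: Environment

    @property
    def n_states(self) -> int:
        return self.M.shape[0]


def _accessible_grid(env: Environment, bin_size: float) -> np.ndarray:
    o = env.origin
    w, h = env.extent
    nx = max(1, round(w / bin_size))
    ny = max(1, round(h / bin_size))
    xs = o.x + (np.arange(nx) + 0.5) * bin_size
    ys = o.y + (np.arange(ny) + 0.5) * bin_size
    gx, gy = np.meshgrid(xs, ys)
    inside = env.contains(gx, gy)
    grid = np.full((ny, nx), -1, dtype=int)
    grid[inside] = np.arange(int(inside.sum()))
    return grid


def tabular_sr(
    env: Environment, gamma: float = 0.95, bin_size: float = STATE_BIN_SIZE
) -> TabularSR:
    """SR of the uniform random walk on the accessible-bin grid.

    Transitions go to the 4 neighbouring bins (uniformly among the
    accessible ones); moves whose straight path crosses a wall or barrier
    are blocked.  M = (I - gamma P)^-1 requires gamma < 1.
    """
    if not (0 <= gamma < 1):
        raise ValueError("gamma must lie in [0, 1)")
    grid = _accessible_grid(env, bin_size)
    ny, nx = grid.shape
    o = env.origin
    centers = {}
    for r in range(ny):
        for c in range(nx):
            if grid[r, c] >= 0:
                centers[grid[r, c]] = np.array(
                    [o.x + (c + 0.5) * bin_size, o.y + (r + 0.5) * bin_size]
                )
    n = len(centers)
    P = np.zeros((n, n))
    segs = env.segments
    for r in range(ny):
        for c in range(nx):
            s = grid[r, c]
            if s < 0:
                continue
            nbrs = []
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < ny and 0 <= cc < nx and grid[rr, cc] >= 0:
                    s2 = grid[rr, cc]
                    if not segment_blocked(centers[s], centers[s2], segs):
                        nbrs.append(s2)
            if nbrs:
                for s2 in nbrs:
                    P[s, s2] = 1.0 / len(nbrs)
            else:
                P[s, s] = 1.0
    M = np.linalg.inv(np.eye(n) - gamma * P)
    return TabularSR(M=M, gamma=gamma, state_grid=grid, bin_size=bin_size, env=env)


def tabular_sr_td(
    env: Environment,
    traj,
    *,
    gamma: float = 0.99,
    alpha: float = 0.01,
    bin_size: float = STATE_BIN_SIZE,
) -> TabularSR:
    """TD-learned tabular SR from a 50 Hz trajectory (parity variant).

    One-hot state features over the accessible-bin grid, updated at every
    trajectory sample with the same per-step discount as the feature model:
    M[:, s_t] += alpha (e_{s_t} + gamma M[:, s_{t+1}] - M[:, s_t]).  Use
    this when contrasting against a TD-learned feature SR so both models
    carry comparable sampling noise.
    """
    grid = _accessible_grid(env, bin_size)
    n = int(grid.max()) + 1
    ny, nx = grid.shape
    # trajectory bins are on the rate-map grid; recompute on the state grid
    o = env.origin
    cc = np.clip(((traj.x - o.x) / bin_size).astype(int), 0, nx - 1)
    rr = np.clip(((traj.y - o.y) / bin_size).astype(int), 0, ny - 1)
    states = grid[rr, cc]
    ok = states >= 0
    # snap rare off-grid samples (bin centers outside the polygon) to the
    # previous valid state
    states = states.copy()
    last = states[ok][0] if ok.any() else 0
    for i in range(states.size):
        if states[i] < 0:
            states[i] = last
        else:
            last = states[i]
    M = np.eye(n)
    for t in range(states.size - 1):
        s, s2 = states[t], states[t + 1]
        M[:, s] += alpha * (gamma * M[:, s2] - M[:, s])
        M[s, s] += alpha
    return TabularSR(M=M, gamma=gamma, state_grid=grid, bin_size=bin_size, env=env)


def _state_map(sr: TabularSR, flat: np.ndarray, normalize: bool = True) -> RateMap:
    vals = np.zeros(sr.state_grid.shape)
    mask = sr.state_grid >= 0
    v = np.maximum(flat, 0.0)
    if normalize and v.max() > 0:
        v = v / v.max()
    vals[mask] = v[sr.state_grid[mask]]
    return RateMap(values=vals, mask=mask, bin_size=sr.bin_size, origin=sr.env.origin)


def baseline_place_map(sr: TabularSR, state: int) -> RateMap:
    """Place map of state s': discounted expected occupancy M[:, s']."""
    if not (0 <= state < sr.n_states):
        raise IndexError("state index out of range")
    return _state_map(sr, sr.M[:, state])


def baseline_eigenmodes(sr: TabularSR) -> list[EigenMode]:
    """Eigenvectors of M sorted by descending real eigenvalue, sign-fixed
    toward the larger positive spatial mass (as in the feature model)."""
    lam, V = np.linalg.eig(sr.M)
    order = np.argsort(-lam.real)
    modes = []
    for rank, k in enumerate(order):
        v = V[:, k].real
        nrm = np.linalg.norm(v)
        if nrm > 0:
            v = v / nrm
        if np.maximum(-v, 0.0).mean() > np.maximum(v, 0.0).mean():
            v = -v
        modes.append(EigenMode(vector=v, eigenvalue=float(lam[k].real), index=rank))
    return modes


def baseline_grid_map(sr: TabularSR, mode: EigenMode) -> RateMap:
    """Grid map: eigenvector thresholded at zero on the state grid."""
    return _state_map(sr, mode.vector)


def baseline_maps(
    sr: TabularSR, *, n_modes: int | None = None
) -> tuple[list[RateMap], list[RateMap]]:
    """(place maps for every state, grid maps for the leading n_modes)."""
    places = [baseline_place_map(sr, s) for s in range(sr.n_states)]
    modes = baseline_eigenmodes(sr)
    if n_modes is not None:
        modes = modes[:n_modes]
    grids = [baseline_grid_map(sr, m) for m in modes]
    return places, grids
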