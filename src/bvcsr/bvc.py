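"""Boundary-vector-cell (BVC) populations and their feature maps.

A BVC fires when an environmental boundary lies at a preferred allocentric
distance d and direction phi from the agent.  Tuning is the product of a
Gaussian in boundary distance (width sigma_rad, growing linearly with d) and
a Gaussian in allocentric direction (constant width sigma_ang).  The firing
rate at a position is the integral of that tuning over all directions, with
the boundary distance in each direction obtained by ray casting.

The population's rate vector f(s) is the basis feature set the successor
matrix is learned over.  Because tuning curves are defined only up to a
proportionality constant, each cell's rate is rescaled to unit peak over the
bin centers of its training environment; those gains are then held fixed
when the environment is manipulated, so that geometric changes show up as
genuine changes in f(s) rather than renormalisation artefacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import Environment, OutOfBoundsError, Point, ray_segment_distances


@dataclass(frozen=True)
class BVC:
    """Preferred distance/direction and tuning widths of one cell."""

    d: float          # preferred boundary distance, m
    phi: float        # preferred allocentric direction, rad in [0, 2pi)
    sigma_rad: float  # radial tuning width, m
    sigma_ang: float  # angular tuning width, rad

    def __post_init__(self) -> None:
        if self.d <= 0 or self.sigma_rad <= 0 or self.sigma_ang <= 0:
            raise ValueError("BVC tuning parameters must be positive")


@dataclass(frozen=True)
class BVCPopulation:
    """Ordered set of BVCs; the ordering fixes the feature indices of the SR.

    Cells are laid out on a polar grid of preferred distances x angles,
    distance-major.  sigma_rad follows the linear rule d/beta + xi.
    """

    cells: tuple[BVC, ...]
    beta: float
    xi: float
    n_dirs: int = 360

    @property
    def n(self) -> int:
        return len(self.cells)

    def as_table(self) -> np.ndarray:
        """(n, 4) array of (d, phi, sigma_rad, sigma_ang) rows."""
        return np.array([[c.d, c.phi, c.sigma_rad, c.sigma_ang] for c in self.cells])


def make_population(
    d_levels=None,
    n_angles: int = 16,
    *,
    beta: float = 12.0,
    xi: float = 0.05,
    sigma_ang: float = 0.2,
    n_dirs: int = 360,
) -> BVCPopulation:
    """Deterministic polar grid of BVC preferences.

    Defaults give 10 preferred distances geometrically spaced in
    [0.05, 0.8] m x 16 uniformly spaced preferred directions = 160 cells.
    """
    if d_levels is None:
        d_levels = np.geomspace(0.05, 0.8, 10)
    d_levels = np.asarray(d_levels, dtype=float)
    if np.any(d_levels <= 0):
        raise ValueError("preferred distances must be positive")
    if n_angles < 1:
        raise ValueError("need at least one preferred angle")
    phis = 2 * np.pi * np.arange(n_angles) / n_angles
    cells = tuple(
        BVC(d=float(d), phi=float(p), sigma_rad=float(d / beta + xi), sigma_ang=sigma_ang)
        for d in d_levels
        for p in phis
    )
    return BVCPopulation(cells=cells, beta=beta, xi=xi, n_dirs=n_dirs)


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to [-pi, pi]."""
    return (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi


def tuning_kernel(cell: BVC, r, theta) -> np.ndarray | float:
    """Tuning density g(r, theta): radial Gaussian x angular Gaussian.

    The radial factor is normalised by d * sqrt(2 pi sigma_rad^2) and the
    angular factor by sqrt(2 pi sigma_ang^2); the absolute scale is
    irrelevant downstream because features are peak-normalised.
    """
    r = np.asarray(r, dtype=float)
    rad = np.exp(-((r - cell.d) ** 2) / (2 * cell.sigma_rad**2)) / (
        cell.d * math.sqrt(2 * math.pi * cell.sigma_rad**2)
    )
    dang = _wrap_angle(np.asarray(theta, dtype=float) - cell.phi)
    ang = np.exp(-(dang**2) / (2 * cell.sigma_ang**2)) / math.sqrt(
        2 * math.pi * cell.sigma_ang**2
    )
    return rad * ang


def _rates_from_distances(pop: BVCPopulation, dists: np.ndarray) -> np.ndarray:
    """Feature rates from per-direction boundary distances.

    dists: (n_pos, n_dirs) ray distances at the population's direction grid.
    Returns (n_pos, n) unnormalised rates.  Exploits the polar-grid layout:
    the radial factor depends only on the distance level, the angular factor
    only on the preferred angle, so the direction sum factorises into one
    matrix product per distance level.
    """
    n_dirs = pop.n_dirs
    thetas = 2 * np.pi * np.arange(n_dirs) / n_dirs
    dtheta = 2 * np.pi / n_dirs
    table = pop.as_table()
    d_levels, level_idx = np.unique(table[:, 0], return_inverse=True)
    rates = np.empty((dists.shape[0], pop.n))
    for li, d in enumerate(d_levels):
        members = np.nonzero(level_idx == li)[0]
        sig = table[members[0], 2]
        rad = np.exp(-((dists - d) ** 2) / (2 * sig**2)) / (
            d * math.sqrt(2 * math.pi * sig**2)
        )  # (n_pos, n_dirs)
        phis = table[members, 1]
        sig_a = table[members, 3][None, :]
        dang = _wrap_angle(thetas[:, None] - phis[None, :])
        ang = np.exp(-(dang**2) / (2 * sig_a**2)) / np.sqrt(2 * np.pi * sig_a**2)
        rates[:, members] = rad @ ang * dtheta
    return rates


def population_rates(pop: BVCPopulation, env: Environment, pos: Point | tuple) -> np.ndarray:
    """Unnormalised feature-rate vector f(s) at a single position.

    Integrates each cell's tuning kernel over n_dirs equally spaced ray
    directions (Riemann sum with weight 2*pi/n_dirs).
    """
    x, y = (pos.x, pos.y) if isinstance(pos, Point) else (float(pos[0]), float(pos[1]))
    if not env.contains(x, y):
        raise OutOfBoundsError(f"position ({x}, {y}) outside {env.name}")
    thetas = 2 * np.pi * np.arange(pop.n_dirs) / pop.n_dirs
    dists = ray_segment_distances(np.array([[x, y]]), thetas, env.segments)
    return _rates_from_distances(pop, dists)[0]


@dataclass(frozen=True)
class FeatureMap:
    """Precomputed feature rates on an environment's bin grid.

    values has shape (ny, nx, n); bins outside the arena hold zeros.  gain
    is the per-cell factor that rescaled the raw rates (unit peak in the
    training environment); pass it on to feature maps of manipulated
    environments so firing remains on the training scale.
    """

    values: np.ndarray
    mask: np.ndarray
    gain: np.ndarray
    env: Environment
    pop: BVCPopulation

    @property
    def n(self) -> int:
        return self.values.shape[2]

    def matrix(self) -> np.ndarray:
        """(n_valid_bins, n) feature matrix over bins inside the arena."""
        return self.values[self.mask]

    def rates_at(self, x, y) -> np.ndarray:
        """Feature vector(s) at position(s) by containing-bin lookup."""
        row, col = self.env.bin_index(x, y)
        return self.values[row, col]


def feature_map(
    pop: BVCPopulation, env: Environment, gain: np.ndarray | None = None
) -> FeatureMap:
    """Evaluate the population rate vector at every bin center inside env.

    With gain=None each cell is rescaled to unit peak over this
    environment's bins (training-environment convention); otherwise the
    provided per-cell gains are applied unchanged.
    """
    xs, ys = env.bin_centers()
    gx, gy = np.meshgrid(xs, ys)
    mask = env.bin_mask()
    positions = np.column_stack([gx[mask], gy[mask]])
    thetas = 2 * np.pi * np.arange(pop.n_dirs) / pop.n_dirs
    # chunk positions to bound the (n_pos, n_dirs) intermediate
    rates = np.empty((positions.shape[0], pop.n))
    chunk = max(1, int(2_000_000 / max(1, pop.n_dirs)))
    for start in range(0, positions.shape[0], chunk):
        sl = slice(start, start + chunk)
        dists = ray_segment_distances(positions[sl], thetas, env.segments)
        rates[sl] = _rates_from_distances(pop, dists)
    if gain is None:
        peaks = rates.max(axis=0)
        peaks[peaks <= 0] = 1.0
        gain = 1.0 / peaks
    rates = rates * gain[None, :]
    values = np.zeros((mask.shape[0], mask.shape[1], pop.n))
    values[mask] = rates
    return FeatureMap(values=values, mask=mask, gain=np.asarray(gain), env=env, pop=pop)
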