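"""Polygonal 2-D arenas with ray-cast boundary distance queries.

Environments are flat polygonal enclosures described by an ordered list of
perimeter walls plus optional internal barriers (partial walls).  All
coordinates are allocentric, in meters, with the origin at the lower-left of
the arena bounding box and angles measured counter-clockwise from the +x
axis, in radians.  The environment also owns the spatial binning used for
rate maps (default 2 cm bins).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon


class InvalidGeometryError(ValueError):
    """Perimeter is open, self-intersecting, or a segment is degenerate."""


class OutOfBoundsError(ValueError):
    """Queried position lies outside (or on the boundary of) the arena."""


@dataclass(frozen=True)
class Point:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("point coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Segment:
    a: Point
    b: Point

    def __post_init__(self) -> None:
        if self.a.x == self.b.x and self.a.y == self.b.y:
            raise InvalidGeometryError("segment endpoints coincide")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a.x, self.a.y], [self.b.x, self.b.y]], dtype=float)

    @property
    def length(self) -> float:
        return math.hypot(self.b.x - self.a.x, self.b.y - self.a.y)


def _segments_to_array(segments: list[Segment]) -> np.ndarray:
    if not segments:
        return np.zeros((0, 2, 2))
    return np.stack([s.as_array() for s in segments])


@dataclass(frozen=True)
class Environment:
    """A closed polygonal arena with optional internal barriers.

    ``walls`` must form a closed, simple outer perimeter; ``barriers`` are
    internal segments that block movement and are seen by boundary-distance
    queries exactly like perimeter walls.
    """

    walls: tuple[Segment, ...]
    barriers: tuple[Segment, ...] = ()
    bin_size: float = 0.02
    name: str = "environment"
    _polygon: Polygon = field(init=False, repr=False, compare=False, default=None)
    _segarray: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        verts = _perimeter_vertices(self.walls)
        poly = Polygon(verts)
        if not poly.is_valid or poly.area <= 0:
            raise InvalidGeometryError("outer perimeter is not a simple closed polygon")
        object.__setattr__(self, "_polygon", poly)
        segs = _segments_to_array(list(self.walls) + list(self.barriers))
        object.__setattr__(self, "_segarray", segs)

    # -- geometry queries ---------------------------------------------------

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def segments(self) -> np.ndarray:
        """All wall and barrier segments, shape (k, 2, 2)."""
        return self._segarray

    @property
    def origin(self) -> Point:
        xmin, ymin, _, _ = self._polygon.bounds
        return Point(xmin, ymin)

    @property
    def extent(self) -> tuple[float, float]:
        xmin, ymin, xmax, ymax = self._polygon.bounds
        return xmax - xmin, ymax - ymin

    def contains(self, x, y) -> np.ndarray:
        """Strict interior test, vectorised over coordinates."""
        return shapely.contains_xy(self._polygon, x, y)

    # -- binning ------------------------------------------------------------

    @property
    def grid_shape(self) -> tuple[int, int]:
        w, h = self.extent
        return (max(1, round(h / self.bin_size)), max(1, round(w / self.bin_size)))

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) of bin-center coordinates along each axis."""
        o = self.origin
        ny, nx = self.grid_shape
        xs = o.x + (np.arange(nx) + 0.5) * self.bin_size
        ys = o.y + (np.arange(ny) + 0.5) * self.bin_size
        return xs, ys

    def bin_mask(self) -> np.ndarray:
        """Boolean (ny, nx) mask of bin centers strictly inside the arena."""
        xs, ys = self.bin_centers()
        gx, gy = np.meshgrid(xs, ys)
        return self.contains(gx, gy)

    def bin_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column bin indices for positions, clipped to the grid."""
        o = self.origin
        ny, nx = self.grid_shape
        col = np.clip(((np.asarray(x) - o.x) / self.bin_size).astype(int), 0, nx - 1)
        row = np.clip(((np.asarray(y) - o.y) / self.bin_size).astype(int), 0, ny - 1)
        return row, col

    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "bin_size": self.bin_size,
            "walls": [s.as_array().tolist() for s in self.walls],
            "barriers": [s.as_array().tolist() for s in self.barriers],
        }
        return json.dumps(doc, indent=1)


def _perimeter_vertices(walls: tuple[Segment, ...]) -> list[tuple[float, float]]:
    """Chain wall segments into an ordered closed vertex loop."""
    if len(walls) < 3:
        raise InvalidGeometryError("perimeter needs at least 3 walls")
    verts = [(walls[0].a.x, walls[0].a.y)]
    cur = (walls[0].b.x, walls[0].b.y)
    tol = 1e-9
    for seg in walls[1:]:
        if math.hypot(seg.a.x - cur[0], seg.a.y - cur[1]) > tol:
            raise InvalidGeometryError("gap in perimeter: walls are not chained")
        verts.append((seg.a.x, seg.a.y))
        cur = (seg.b.x, seg.b.y)
    first = (walls[0].a.x, walls[0].a.y)
    if math.hypot(cur[0] - first[0], cur[1] - first[1]) > tol:
        raise InvalidGeometryError("perimeter is not closed")
    return verts


def _walls_from_vertices(verts: list[tuple[float, float]]) -> tuple[Segment, ...]:
    segs = []
    for i in range(len(verts)):
        a = verts[i]
        b = verts[(i + 1) % len(verts)]
        segs.append(Segment(Point(*a), Point(*b)))
    return tuple(segs)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _rect_vertices(width: float, height: float) -> list[tuple[float, float]]:
    return [(0.0, 0.0), (width, 0.0), (width, height), (0.0, height)]


def build_environment(
    spec: str | list = "square",
    *,
    bin_size: float = 0.02,
    width: float = 1.0,
    height: float = 1.0,
    circle_sides: int = 64,
    trapezoid_sides: tuple[float, float] = (0.9, 0.2),
    trapezoid_length: float = 1.9,
    hairpin_size: float = 2.0,
    hairpin_walls: int = 7,
    hairpin_gap: float = 0.2,
    name: str | None = None,
) -> Environment:
    """Build a named preset arena or an explicit closed wall list.

    Presets: ``square`` (1 m x 1 m, or ``width`` x ``height``), ``rect``
    (alias with explicit dimensions), ``circle`` (regular polygon
    approximation, default 64-gon, 1 m diameter scaled by ``width``),
    ``trapezoid`` (parallel vertical ends of heights ``trapezoid_sides``,
    horizontal length ``trapezoid_length``), and ``hairpin`` (square maze
    with alternating internal walls forming U-turn channels).

    An explicit ``spec`` is a list of vertices ``[(x, y), ...]`` or of
    segments ``[((x0,y0),(x1,y1)), ...]`` forming a closed simple perimeter.
    """
    if isinstance(spec, str):
        barriers: tuple[Segment, ...] = ()
        if spec in ("square", "rect"):
            verts = _rect_vertices(width, height)
        elif spec == "circle":
            r = width / 2.0
            ang = 2 * np.pi * (np.arange(circle_sides) + 0.5) / circle_sides
            verts = [(r + r * math.cos(a), r + r * math.sin(a)) for a in ang]
        elif spec == "trapezoid":
            broad, narrow = trapezoid_sides
            length = trapezoid_length
            # broad end at x = 0, narrow end at x = length, centered vertically
            ymid = broad / 2.0
            verts = [
                (0.0, 0.0),
                (length, ymid - narrow / 2.0),
                (length, ymid + narrow / 2.0),
                (0.0, broad),
            ]
        elif spec == "hairpin":
            size = hairpin_size
            verts = _rect_vertices(size, size)
            n = hairpin_walls
            pitch = size / (n + 1)
            walls = []
            for k in range(1, n + 1):
                x = k * pitch
                if k % 2 == 1:  # attached to bottom, gap at top
                    walls.append(Segment(Point(x, 0.0), Point(x, size - hairpin_gap)))
                else:  # attached to top, gap at bottom
                    walls.append(Segment(Point(x, hairpin_gap), Point(x, size)))
            barriers = tuple(walls)
        else:
            raise ValueError(f"unknown preset {spec!r}")
        env_name = name or spec
        return Environment(_walls_from_vertices(verts), barriers, bin_size, env_name)

    # explicit wall list
    items = list(spec)
    if not items:
        raise InvalidGeometryError("empty wall list")
    if isinstance(items[0], Segment):
        walls = tuple(items)
    elif np.shape(items[0]) == (2, 2):
        walls = tuple(Segment(Point(*a), Point(*b)) for a, b in items)
    else:
        walls = _walls_from_vertices([tuple(map(float, v)) for v in items])
    return Environment(walls, (), bin_size, name or "custom")


# ---------------------------------------------------------------------------
# Ray casting
# ---------------------------------------------------------------------------

def ray_segment_distances(
    origins: np.ndarray, angles: np.ndarray, segments: np.ndarray
) -> np.ndarray:
    """Distance from each origin along each direction to the nearest segment.

    Parameters
    ----------
    origins : (n, 2) array of ray origins.
    angles : (m,) array of allocentric directions, radians.
    segments : (k, 2, 2) array of segment endpoints.

    Returns
    -------
    (n, m) array of distances (inf where no segment is hit).
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    dx = np.cos(angles)[None, :]  # (1, m)
    dy = np.sin(angles)[None, :]
    best = np.full((origins.shape[0], angles.size), np.inf)
    ox = origins[:, 0][:, None]
    oy = origins[:, 1][:, None]
    for seg in segments:
        (ax, ay), (bx, by) = seg
        ex, ey = bx - ax, by - ay
        # solve o + t*d = a + u*e  for t >= 0, 0 <= u <= 1
        denom = dx * ey - dy * ex  # (n, m)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = ((ax - ox) * ey - (ay - oy) * ex) / denom
            u = ((ax - ox) * dy - (ay - oy) * dx) / denom
        hit = (np.abs(denom) > 1e-14) & (t > 1e-12) & (u >= -1e-12) & (u <= 1 + 1e-12)
        best = np.where(hit & (t < best), t, best)
    return best


def ray_distance(env: Environment, pos: Point | tuple, theta) -> float | np.ndarray:
    """Distance from an interior position to the nearest wall or barrier
    along allocentric direction(s) ``theta``.

    Barriers are opaque: only the first intersection along the ray counts.
    """
    x, y = (pos.x, pos.y) if isinstance(pos, Point) else (float(pos[0]), float(pos[1]))
    if not env.contains(x, y):
        raise OutOfBoundsError(f"position ({x}, {y}) is not strictly inside {env.name}")
    d = ray_segment_distances(np.array([[x, y]]), np.asarray(theta, dtype=float), env.segments)
    d = d[0]
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return float(d[0])
    return d


# ---------------------------------------------------------------------------
# Manipulations
# ---------------------------------------------------------------------------

def _scale_point(p: Point, ox: float, oy: float, fx: float, fy: float) -> Point:
    return Point(ox + (p.x - ox) * fx, oy + (p.y - oy) * fy)


def scale_environment(env: Environment, fx: float, fy: float) -> Environment:
    """Stretch or compress the arena about its bounding-box origin.

    All wall and barrier endpoints are scaled by (fx, fy); the rate-map bin
    size is unchanged, so the bin grid grows or shrinks with the arena.
    """
    if fx <= 0 or fy <= 0:
        raise ValueError("scale factors must be positive")
    o = env.origin
    walls = tuple(
        Segment(_scale_point(s.a, o.x, o.y, fx, fy), _scale_point(s.b, o.x, o.y, fx, fy))
        for s in env.walls
    )
    barriers = tuple(
        Segment(_scale_point(s.a, o.x, o.y, fx, fy), _scale_point(s.b, o.x, o.y, fx, fy))
        for s in env.barriers
    )
    return Environment(walls, barriers, env.bin_size, f"{env.name}_x{fx:g}_y{fy:g}")


def insert_barrier(env: Environment, seg: Segment) -> Environment:
    """Return a new environment with ``seg`` added as an internal barrier.

    The segment must lie inside the perimeter (endpoints may touch it); the
    original environment is untouched.
    """
    ls = shapely.LineString([(seg.a.x, seg.a.y), (seg.b.x, seg.b.y)])
    # allow endpoints on the perimeter but no part outside
    if not env.polygon.buffer(1e-9).contains(ls):
        raise InvalidGeometryError("barrier crosses or lies outside the perimeter")
    return Environment(
        env.walls, env.barriers + (seg,), env.bin_size, f"{env.name}+barrier"
    )


def default_barrier(env: Environment) -> Segment:
    """Vertical barrier from the midpoint of the bottom wall halfway across."""
    o = env.origin
    w, h = env.extent
    return Segment(Point(o.x + w / 2.0, o.y), Point(o.x + w / 2.0, o.y + h / 2.0))


def segment_blocked(p0: np.ndarray, p1: np.ndarray, segments: np.ndarray) -> bool:
    """True if the straight move from p0 to p1 crosses any segment."""
    d = p1 - p0
    dist = ray_segment_distances(p0[None, :], np.array([math.atan2(d[1], d[0])]), segments)
    step = math.hypot(d[0], d[1])
    return bool(dist[0, 0] <= step + 1e-12)


def equal_area_split_x(env: Environment) -> float:
    """x-coordinate of the vertical line dividing the arena into equal areas."""
    from scipy.optimize import brentq

    xmin, ymin, xmax, ymax = env.polygon.bounds
    total = env.polygon.area

    def left_area(x):
        box = shapely.box(xmin - 1.0, ymin - 1.0, x, ymax + 1.0)
        return env.polygon.intersection(box).area - total / 2.0

    return float(brentq(left_area, xmin + 1e-9, xmax - 1e-9, xtol=1e-10))
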