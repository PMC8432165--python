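"""Place-field detection and field-level event analyses.

Covers detection of fields as connected suprathreshold components, the
barrier-insertion duplication bookkeeping (immediate duplication, loss
after relearning, reversion after removal), cross-environment field-size
comparison under arena rescaling, and the arm-by-arm correlation structure
of maps in a hairpin maze.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cells import RateMap
from .geometry import Point, Segment

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
MIN_ARM_BINS = 20


@dataclass(frozen=True)
class PlaceField:
    """One connected firing field of a rate map."""

    bins: np.ndarray      # (k, 2) array of (row, col) bin indices
    peak_rate: float
    centroid: Point       # rate-weighted, in meters
    area: float           # m^2

    @property
    def n_bins(self) -> int:
        return self.bins.shape[0]


@dataclass(frozen=True)
class DuplicationRecord:
    """Per-cell bookkeeping for the barrier-insertion protocol."""

    cell: int
    fields_before: int
    fields_after_insertion: int
    duplicated: bool
    persisted: bool | None = None   # after relearning with the barrier
    reverted: bool | None = None    # after barrier removal


def detect_fields(rate_map: RateMap, min_area: float = 0.0036) -> list[PlaceField]:
    """Connected components of positive-rate bins, 4-connected.

    Maps arriving here are already thresholded (place maps at 80% of max,
    grid maps at zero), so any positive bin belongs to a field.  Components
    smaller than ``min_area`` (default 9 bins of 2 cm) are speckle and
    discarded.  Fields are sorted by descending peak rate.
    """
    active = rate_map.mask & (rate_map.values > 0)
    lab, n = ndimage.label(active, structure=FOUR_CONNECTED)
    min_bins = max(1, round(min_area / rate_map.bin_size**2))
    fields = []
    for k in range(1, n + 1):
        rows, cols = np.nonzero(lab == k)
        if rows.size < min_bins:
            continue
        w = rate_map.values[rows, cols]
        cx = rate_map.origin.x + (np.average(cols, weights=w) + 0.5) * rate_map.bin_size
        cy = rate_map.origin.y + (np.average(rows, weights=w) + 0.5) * rate_map.bin_size
        fields.append(
            PlaceField(
                bins=np.column_stack([rows, cols]),
                peak_rate=float(w.max()),
                centroid=Point(float(cx), float(cy)),
                area=float(rows.size * rate_map.bin_size**2),
            )
        )
    fields.sort(key=lambda f: -f.peak_rate)
    return fields


def _barrier_side(field: PlaceField, barrier: Segment) -> int:
    """-1/+1 for the side of the barrier's supporting line; 0 if outside the
    barrier's bounding strip (unassigned)."""
    a, b = barrier.a, barrier.b
    ex, ey = b.x - a.x, b.y - a.y
    px, py = field.centroid.x - a.x, field.centroid.y - a.y
    # projection along the barrier must fall within the segment extent
    t = (px * ex + py * ey) / (ex * ex + ey * ey)
    if not (0.0 <= t <= 1.0):
        return 0
    cross = ex * py - ey * px
    if cross == 0:
        return 0
    return 1 if cross > 0 else -1


def barrier_duplication(
    map_before: RateMap,
    map_after: RateMap,
    barrier: Segment,
    *,
    cell: int = -1,
    min_area: float = 0.0036,
) -> DuplicationRecord:
    """Did barrier insertion immediately create an additional field?

    Duplication requires (i) more fields after insertion than before and
    (ii) at least one field strictly on each side of the barrier's
    supporting line, sides judged by centroid signed distance and only
    within the barrier's bounding strip.
    """
    if map_before.values.shape != map_after.values.shape:
        raise ValueError("maps do not share bin geometry")
    before = detect_fields(map_before, min_area)
    after = detect_fields(map_after, min_area)
    sides = {_barrier_side(f, barrier) for f in after}
    duplicated = (len(after) > len(before)) and ({-1, 1} <= sides)
    return DuplicationRecord(
        cell=cell,
        fields_before=len(before),
        fields_after_insertion=len(after),
        duplicated=duplicated,
    )


def field_size_comparison(
    maps_by_env: dict[str, list[RateMap]], *, min_area: float = 0.0036
) -> tuple[dict[str, np.ndarray], dict[tuple[str, str], float]]:
    """Per-cell total field area in each environment, and their correlations.

    Returns (areas, correlations): ``areas[env]`` is the per-cell total
    field area vector; ``correlations[(env_a, env_b)]`` the Pearson
    correlation of per-cell areas over cells with fields in both arenas
    (NaN when fewer than 2 such cells).
    """
    names = list(maps_by_env)
    if len(names) < 2:
        raise ValueError("need at least two environments")
    n_cells = len(maps_by_env[names[0]])
    areas = {}
    for name in names:
        maps = maps_by_env[name]
        if len(maps) != n_cells:
            raise ValueError("environments have differing cell counts")
        areas[name] = np.array(
            [sum(f.area for f in detect_fields(m, min_area)) for m in maps]
        )
    corr: dict[tuple[str, str], float] = {}
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            both = (areas[na] > 0) & (areas[nb] > 0)
            if both.sum() < 2:
                corr[(na, nb)] = float("nan")
                continue
            a, b = areas[na][both], areas[nb][both]
            if a.std() == 0 or b.std() == 0:
                corr[(na, nb)] = float("nan")
            else:
                corr[(na, nb)] = float(np.corrcoef(a, b)[0, 1])
    return areas, corr


def hairpin_arm_masks(env, n_arms: int | None = None) -> list[np.ndarray]:
    """Bin masks of the vertical channels of a hairpin maze, left to right.

    Channels are the strips between consecutive internal walls (and the
    outer side walls); each mask excludes bins outside the arena.
    """
    mask = env.bin_mask()
    xs, _ = env.bin_centers()
    wall_x = sorted(s.a.x for s in env.barriers)
    o = env.origin
    w, _ = env.extent
    edges = [o.x] + wall_x + [o.x + w]
    if n_arms is not None and len(edges) - 1 != n_arms:
        raise ValueError("wall count does not match requested arm count")
    masks = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        col_sel = (xs > lo) & (xs < hi)
        m = mask & col_sel[None, :]
        masks.append(m)
    return masks


def arm_correlation_matrix(
    rate_map: RateMap, arm_masks: list[np.ndarray], *, align_alternating: bool = True
) -> np.ndarray:
    """Pearson correlations between a map's restriction to congruent arms.

    Arms are resampled onto a common frame by cropping each arm's bounding
    box to the smallest common (height, width); with ``align_alternating``
    odd-indexed arms are flipped vertically so all arms are expressed in a
    common traversal direction (the agent runs alternate channels in
    opposite directions).  Entries are NaN for degenerate (constant) arms.
    """
    patches = []
    shapes = []
    for m in arm_masks:
        if m.sum() < MIN_ARM_BINS:
            raise ValueError("arm has too few valid bins")
        rows, cols = np.nonzero(m)
        patch = np.where(m, rate_map.values, np.nan)[
            rows.min() : rows.max() + 1, cols.min() : cols.max() + 1
        ]
        patches.append(patch)
        shapes.append(patch.shape)
    h = min(s[0] for s in shapes)
    w = min(s[1] for s in shapes)
    aligned = []
    for i, p in enumerate(patches):
        # center-crop to the common frame
        r0 = (p.shape[0] - h) // 2
        c0 = (p.shape[1] - w) // 2
        q = p[r0 : r0 + h, c0 : c0 + w]
        if align_alternating and i % 2 == 1:
            q = q[::-1, :]
        aligned.append(q)
    n = len(aligned)
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            a, b = aligned[i], aligned[j]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < MIN_ARM_BINS:
                continue
            av, bv = a[ok], b[ok]
            if av.std() == 0 or bv.std() == 0:
                continue
            out[i, j] = out[j, i] = float(np.corrcoef(av, bv)[0, 1])
    return out
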