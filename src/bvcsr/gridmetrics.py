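"""Spatial autocorrelograms and grid-structure metrics.

Implements the standard grid-cell analysis chain: masked-Pearson spatial
autocorrelogram (SAC), expanding-annulus gridness (60-degree rotational
correlation contrast), grid axis orientation from the nearest SAC peak,
ellipse fits to the six central peaks (field ellipticity), coefficient of
variability of per-field peak rates, a shuffled-gridness classification
criterion, and the KL divergence of an orientation distribution from
uniform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.feature import peak_local_max

from .cells import RateMap

MIN_OVERLAP_BINS = 20


@dataclass(frozen=True)
class Autocorrelogram:
    """2-D Pearson autocorrelation of a rate map over all integer lags.

    values is (2*ny-1, 2*nx-1) with NaN where fewer than MIN_OVERLAP_BINS
    bin pairs overlap; center is the zero-lag index (value 1 by construction).
    """

    values: np.ndarray
    center: tuple[int, int]
    bin_size: float

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def lag_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(dy, dx) integer lag offsets of every SAC bin."""
        cy, cx = self.center
        dy = np.arange(self.values.shape[0])[:, None] - cy
        dx = np.arange(self.values.shape[1])[None, :] - cx
        return np.broadcast_arrays(dy, dx)


def _xcorr_full(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return fftconvolve(a, b[::-1, ::-1], mode="full")


def sac(rate_map: RateMap, min_overlap: int = MIN_OVERLAP_BINS) -> Autocorrelogram:
    """Masked Pearson spatial autocorrelogram.

    At each 2-D lag only bin pairs valid in both shifted copies enter the
    correlation; lags supported by fewer than ``min_overlap`` pairs are NaN.
    A constant map has undefined correlations everywhere except zero lag.
    """
    m = rate_map.mask.astype(float)
    if m.sum() < 2:
        raise ValueError("need at least 2 valid bins")
    z = np.where(rate_map.mask, rate_map.values, 0.0)
    n = np.rint(_xcorr_full(m, m))
    sx = _xcorr_full(z, m)
    sy = _xcorr_full(m, z)
    sxx = _xcorr_full(z * z, m)
    syy = _xcorr_full(m, z * z)
    sxy = _xcorr_full(z, z)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        var_x = n * sxx - sx * sx
        var_y = n * syy - sy * sy
        r = cov / np.sqrt(var_x * var_y)
    r[(n < min_overlap) | (var_x <= 1e-12) | (var_y <= 1e-12)] = np.nan
    cy, cx = rate_map.mask.shape[0] - 1, rate_map.mask.shape[1] - 1
    if np.isfinite(r[cy, cx]):
        r[cy, cx] = 1.0
    return Autocorrelogram(values=r, center=(cy, cx), bin_size=rate_map.bin_size)


def sac_correlation(a: Autocorrelogram, b: Autocorrelogram) -> float:
    """Pearson correlation between two SACs over jointly valid lag bins.

    The SACs are aligned on their centers; the smaller array defines the
    overlapping lag window.
    """
    hy = min(a.center[0], b.center[0])
    hx = min(a.center[1], b.center[1])

    def crop(s: Autocorrelogram) -> np.ndarray:
        cy, cx = s.center
        return s.values[cy - hy : cy + hy + 1, cx - hx : cx + hx + 1]

    va, vb = crop(a), crop(b)
    ok = np.isfinite(va) & np.isfinite(vb)
    if ok.sum() < MIN_OVERLAP_BINS:
        return float("nan")
    va, vb = va[ok], vb[ok]
    if va.std() == 0 or vb.std() == 0:
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


# ---------------------------------------------------------------------------
# Gridness
# ---------------------------------------------------------------------------

def _central_peak_radius(acg: Autocorrelogram) -> int:
    """Extent (in bins) of the central SAC peak.

    Radius of the connected region around zero lag with correlation above
    0.2, plus one bin; capped at 40% of the largest usable radius.
    """
    vals = np.nan_to_num(acg.values, nan=-1.0)
    above = vals > 0.2
    lab, _ = ndimage.label(above)
    cy, cx = acg.center
    central = lab == lab[cy, cx]
    dy, dx = acg.lag_grid()
    rr = np.hypot(dy, dx)
    r_max = min(cy, cx)
    radius = int(np.ceil(rr[central].max())) + 1 if central.any() else 2
    return int(min(max(radius, 2), max(2, 0.4 * r_max)))


def _rotated_stack(acg: Autocorrelogram, angles_deg) -> list[tuple[np.ndarray, np.ndarray]]:
    vals = np.nan_to_num(acg.values, nan=0.0)
    valid = acg.valid.astype(float)
    out = []
    for ang in angles_deg:
        rv = ndimage.rotate(vals, ang, reshape=False, order=1, mode="constant", cval=0.0)
        rm = ndimage.rotate(valid, ang, reshape=False, order=1, mode="constant", cval=0.0)
        out.append((rv, rm > 0.99))
    return out


def gridness(acg: Autocorrelogram, *, inner_radius: int | None = None) -> float:
    """Expanding-annulus gridness score.

    For annuli excluding the central peak and sweeping the outer radius, the
    SAC is correlated with itself rotated by 30/60/90/120/150 degrees over
    the annulus; the score for an annulus is min(r60, r120) - max(r30, r90,
    r150) and the reported gridness is the best score over annuli.  Returns
    NaN when no annulus has enough valid bins.
    """
    inner = inner_radius if inner_radius is not None else _central_peak_radius(acg)
    cy, cx = acg.center
    r_max = min(cy, cx)
    if inner + 3 > r_max:
        return float("nan")
    dy, dx = acg.lag_grid()
    rr = np.hypot(dy, dx)
    rot = _rotated_stack(acg, (30, 60, 90, 120, 150))
    vals = np.nan_to_num(acg.values, nan=0.0)
    valid = acg.valid
    best = float("nan")
    outer_radii = np.unique(np.linspace(inner + 3, r_max, 12).astype(int))
    for outer in outer_radii:
        ring = (rr > inner) & (rr <= outer) & valid
        corrs = []
        for rv, rm in rot:
            sel = ring & rm
            if sel.sum() < MIN_OVERLAP_BINS:
                corrs.append(np.nan)
                continue
            x, y_ = vals[sel], rv[sel]
            if x.std() == 0 or y_.std() == 0:
                corrs.append(np.nan)
                continue
            corrs.append(float(np.corrcoef(x, y_)[0, 1]))
        r30, r60, r90, r120, r150 = corrs
        if any(np.isnan(c) for c in corrs):
            continue
        score = min(r60, r120) - max(r30, r90, r150)
        if np.isnan(best) or score > best:
            best = score
    return best


# ---------------------------------------------------------------------------
# SAC peaks, orientation, ellipticity
# ---------------------------------------------------------------------------

def sac_peaks(
    acg: Autocorrelogram,
    *,
    min_corr: float = 0.1,
    min_separation: int = 3,
    exclude_central: bool = True,
) -> np.ndarray:
    """Off-center local maxima of the SAC as (dy, dx) lag offsets.

    Peaks are local maxima above ``min_corr`` correlation separated by at
    least ``min_separation`` bins; the central peak region is excluded.
    Sorted by distance from the center.
    """
    vals = np.nan_to_num(acg.values, nan=-1.0)
    coords = peak_local_max(
        vals, min_distance=min_separation, threshold_abs=min_corr, exclude_border=False
    )
    if coords.size == 0:
        return np.zeros((0, 2))
    cy, cx = acg.center
    offs = coords.astype(float)
    # parabolic sub-bin refinement along each axis (peaks sit between bins)
    for k, (r, c) in enumerate(coords):
        if 0 < r < vals.shape[0] - 1:
            denom = vals[r - 1, c] - 2 * vals[r, c] + vals[r + 1, c]
            if denom < 0:
                offs[k, 0] += np.clip(0.5 * (vals[r - 1, c] - vals[r + 1, c]) / denom, -0.5, 0.5)
        if 0 < c < vals.shape[1] - 1:
            denom = vals[r, c - 1] - 2 * vals[r, c] + vals[r, c + 1]
            if denom < 0:
                offs[k, 1] += np.clip(0.5 * (vals[r, c - 1] - vals[r, c + 1]) / denom, -0.5, 0.5)
    offs = offs - np.array([cy, cx])
    rr = np.hypot(offs[:, 0], offs[:, 1])
    keep = rr > (_central_peak_radius(acg) if exclude_central else 0)
    offs, rr = offs[keep], rr[keep]
    return offs[np.argsort(rr)]


def grid_orientation(acg: Autocorrelogram) -> float:
    """Axis orientation: angle to the nearest off-center SAC peak, mod 60 deg.

    Returns radians in [0, pi/3); NaN when no peak is detectable.
    """
    peaks = sac_peaks(acg)
    if peaks.shape[0] == 0:
        return float("nan")
    dy, dx = peaks[0]
    ang = math.atan2(dy, dx)
    return ang % (math.pi / 3)


def _fit_centered_ellipse(points: np.ndarray) -> tuple[float, float]:
    """Least-squares centered conic a x^2 + b xy + c y^2 = 1 through points.

    Returns (semi_major, semi_minor).  Raises on non-elliptical fits.
    """
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([x * x, x * y, y * y])
    coef, *_ = np.linalg.lstsq(A, np.ones_like(x), rcond=None)
    a, b, c = coef
    Q = np.array([[a, b / 2], [b / 2, c]])
    ev = np.linalg.eigvalsh(Q)
    if np.any(ev <= 0):
        raise ValueError("fit is not an ellipse")
    axes = 1.0 / np.sqrt(ev)  # descending: ev ascending -> axes descending
    return float(axes[0]), float(axes[1])


def ellipticity(acg: Autocorrelogram, *, n_peaks: int = 6) -> float:
    """Eccentricity of the ellipse through the six central SAC peaks.

    0 for peaks on a perfect circle, sqrt(1 - (b/a)^2) in general.  NaN when
    fewer than ``n_peaks`` peaks are detectable or the fit degenerates.
    """
    peaks = sac_peaks(acg)
    if peaks.shape[0] < n_peaks:
        return float("nan")
    pts = peaks[:n_peaks].astype(float)[:, ::-1]  # (dx, dy)
    try:
        a, b = _fit_centered_ellipse(pts)
    except (ValueError, np.linalg.LinAlgError):
        return float("nan")
    return math.sqrt(max(0.0, 1.0 - (b / a) ** 2))


# ---------------------------------------------------------------------------
# Field-rate variability
# ---------------------------------------------------------------------------

def peak_cv(rate_map: RateMap, *, field_threshold: float = 0.5) -> float:
    """Coefficient of variability of per-field peak rates (sample SD / mean).

    Fields are connected components of bins above ``field_threshold`` x the
    map peak.  NaN with fewer than two fields.
    """
    if rate_map.is_degenerate:
        return float("nan")
    above = rate_map.mask & (rate_map.values > field_threshold * rate_map.peak)
    lab, n_fields = ndimage.label(above)
    if n_fields < 2:
        return float("nan")
    peaks = ndimage.labeled_comprehension(
        rate_map.values, lab, np.arange(1, n_fields + 1), np.max, float, np.nan
    )
    mean = peaks.mean()
    if mean == 0:
        return float("nan")
    return float(peaks.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# Shuffled gridness criterion
# ---------------------------------------------------------------------------

def shuffled_gridness_threshold(
    modes,
    fmap,
    *,
    n_shuffles: int = 200,
    percentile: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> float:
    """Null gridness threshold from weight-shuffled eigenvectors.

    Each null sample permutes one eigenvector's weights across BVC
    identities (preserving the weight distribution, destroying spatial
    coherence), rebuilds the thresholded map and scores its gridness;
    shuffles cycle over the supplied modes and the pooled null distribution's
    ``percentile`` is returned.  A mode whose gridness exceeds this
    threshold is classified as a grid cell.
    """
    from .cells import EigenMode, grid_map

    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles for a stable percentile")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = []
    n_modes = len(modes)
    k = 0
    attempts = 0
    while len(scores) < n_shuffles and attempts < 5 * n_shuffles:
        attempts += 1
        mode = modes[k % n_modes]
        k += 1
        v = rng.permutation(mode.vector)
        gm = grid_map(EigenMode(vector=v, eigenvalue=mode.eigenvalue, index=mode.index), fmap)
        if gm.is_degenerate:
            continue
        g = gridness(sac(gm))
        if np.isfinite(g):
            scores.append(g)
    if len(scores) < n_shuffles // 2:
        raise RuntimeError("too few valid null gridness scores")
    return float(np.percentile(scores, percentile))


# ---------------------------------------------------------------------------
# Orientation distribution
# ---------------------------------------------------------------------------

def kl_uniform(orientations, n_bins: int = 20) -> float:
    """KL divergence (nats) of grid-axis orientations from uniform.

    Orientations (radians, taken mod 60 degrees) are histogrammed into
    ``n_bins`` equal bins over [0, pi/3); D = sum p ln(p / (1/n_bins)) with
    empty bins contributing zero.
    """
    orientations = np.asarray([o for o in np.atleast_1d(orientations) if np.isfinite(o)])
    if orientations.size == 0:
        raise ValueError("no orientations supplied")
    if n_bins < 2:
        raise ValueError("need at least 2 histogram bins")
    wrapped = np.mod(orientations, math.pi / 3)
    counts, _ = np.histogram(wrapped, bins=n_bins, range=(0.0, math.pi / 3))
    p = counts / counts.sum()
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] * n_bins)))
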