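"""Place-cell and grid-cell rate maps derived from the successor matrix.

Place cells are modelled as successor features: the firing of cell i at
position s is the thresholded row-i weighted sum of BVC rates,
F_i(s) = relu(sum_j M[i, j] f_j(s) - T), with T at 80% of the cell's
maximum activation.  Grid cells are thresholded eigenvectors of M
projected back through the BVC features, G_i(s) = relu(sum_j v_ij f_j(s)),
a low-dimensional embedding of the successor features.
All maps are peak-normalised (the model fixes rates only up to scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bvc import FeatureMap
from .geometry import Point
from .sr import SuccessorMatrix

PLACE_THRESHOLD_FRACTION = 0.8


@dataclass(frozen=True)
class RateMap:
    """2-D binned firing-rate surface with an inside-arena validity mask."""

    values: np.ndarray
    mask: np.ndarray
    bin_size: float
    origin: Point

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    @property
    def peak(self) -> float:
        v = self.values[self.mask]
        return float(v.max()) if v.size else 0.0

    @property
    def is_degenerate(self) -> bool:
        """All-zero (or empty) after thresholding; excluded from statistics."""
        return self.peak <= 0.0

    def masked(self) -> np.ndarray:
        """values with NaN outside the arena."""
        out = np.where(self.mask, self.values, np.nan)
        return out

    def restrict(self, submask: np.ndarray) -> "RateMap":
        """Same surface with validity limited to mask AND submask."""
        return RateMap(self.values, self.mask & submask, self.bin_size, self.origin)


@dataclass(frozen=True)
class EigenMode:
    """One eigenvector of the successor matrix, ranked by eigenvalue."""

    vector: np.ndarray  # unit norm, sign-fixed, real
    eigenvalue: float   # real part
    index: int          # 0 = largest real eigenvalue

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        object.__setattr__(self, "vector", v)


def _as_ratemap(flat: np.ndarray, fmap: FeatureMap, normalize: bool = True) -> RateMap:
    values = np.zeros(fmap.mask.shape)
    v = np.maximum(flat, 0.0)
    if normalize and v.max() > 0:
        v = v / v.max()
    values[fmap.mask] = v
    return RateMap(
        values=values, mask=fmap.mask.copy(), bin_size=fmap.env.bin_size, origin=fmap.env.origin
    )


def place_map(sm: SuccessorMatrix, i: int, fmap: FeatureMap) -> RateMap:
    """Thresholded successor-feature map of place cell i.

    raw(s) = sum_j M[i, j] f_j(s); the threshold is 80% of the maximum of
    raw over valid bins, and the suprathreshold remainder is peak-normalised.
    """
    if not (0 <= i < sm.n):
        raise IndexError(f"cell index {i} out of range")
    r = fmap.matrix() @ sm.M[i]
    T = PLACE_THRESHOLD_FRACTION * r.max()
    return _as_ratemap(np.maximum(r - T, 0.0) if r.max() > 0 else r * 0.0, fmap)


def place_maps(sm: SuccessorMatrix, fmap: FeatureMap) -> list[RateMap]:
    """All n place maps at once (single matrix product over the bin grid)."""
    F = fmap.matrix()  # (nbins, n)
    raw = F @ sm.M.T   # (nbins, n), column i = activation of cell i
    out = []
    for i in range(sm.n):
        r = raw[:, i]
        T = PLACE_THRESHOLD_FRACTION * r.max()
        out.append(_as_ratemap(np.maximum(r - T, 0.0) if r.max() > 0 else r * 0.0, fmap))
    return out


def sr_eigenmodes(sm: SuccessorMatrix, fmap: FeatureMap | None = None) -> list[EigenMode]:
    """Eigen decomposition of M, sorted by descending real eigenvalue.

    M is generally non-symmetric, so eigenpairs may be complex; the real
    parts are kept.  Each vector is unit-normalised and sign-fixed: with a
    feature map, the sign giving the larger spatial mean of the thresholded
    map relu(F v) is chosen; without one, the largest-magnitude component is
    made positive.
    """
    lam, V = np.linalg.eig(sm.M)
    order = np.argsort(-lam.real)
    F = fmap.matrix() if fmap is not None else None
    modes = []
    for rank, k in enumerate(order):
        v = V[:, k].real
        nrm = np.linalg.norm(v)
        if nrm > 0:
            v = v / nrm
        if F is not None:
            pos = np.maximum(F @ v, 0.0).mean()
            neg = np.maximum(F @ -v, 0.0).mean()
            if neg > pos:
                v = -v
        elif v[np.argmax(np.abs(v))] < 0:
            v = -v
        modes.append(EigenMode(vector=v, eigenvalue=float(lam[k].real), index=rank))
    return modes


def grid_map(mode: EigenMode, fmap: FeatureMap) -> RateMap:
    """Thresholded eigenvector map G(s) = relu(sum_j v_j f_j(s)), unit peak."""
    if mode.vector.shape[0] != fmap.n:
        raise ValueError("eigenvector length does not match the feature map")
    F = fmap.matrix()
    return _as_ratemap(F @ mode.vector, fmap)


def grid_maps(modes: list[EigenMode], fmap: FeatureMap) -> list[RateMap]:
    return [grid_map(m, fmap) for m in modes]
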