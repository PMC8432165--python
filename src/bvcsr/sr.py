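"""Temporal-difference learning of a successor representation over BVC features.

The successor matrix M maps the current feature-rate vector f(s) to the
discounted expected sum of future feature vectors, psi(s) = M f(s)
(successor features).  M is learned online from 50 Hz trajectories with the
linear-function-approximation TD rule

    M <- M + alpha_M (f(s_t) + gamma psi(s_{t+1}) - psi(s_t)) f(s_t)^T

Reward weights R are learned by an analogous TD rule on the value
V(s) = psi(s)^T R; all spatial-representation experiments here run with
R = 0 (latent learning), so the reward machinery is exercised but inert.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bvc import FeatureMap
from .motion import Trajectory


@dataclass(frozen=True)
class SuccessorMatrix:
    """n x n successor matrix over feature indices.

    M[i, j] weights how strongly feature j's current firing predicts
    feature i's discounted future firing.  gamma is the per-step (20 ms)
    discount; alpha_M the TD learning rate.
    """

    M: np.ndarray
    gamma: float = 0.99
    alpha_M: float = 0.01
    updates: int = 0

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("M must be square")
        if not np.all(np.isfinite(M)):
            raise ValueError("M must be finite")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        object.__setattr__(self, "M", M)

    @property
    def n(self) -> int:
        return self.M.shape[0]

    @classmethod
    def identity(cls, n: int, gamma: float = 0.99, alpha_M: float = 0.01) -> "SuccessorMatrix":
        """Zero-knowledge prior: psi includes the t=0 term, so M0 = I."""
        return cls(M=np.eye(n), gamma=gamma, alpha_M=alpha_M)


@dataclass(frozen=True)
class RewardWeights:
    R: np.ndarray
    alpha_R: float = 0.01

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 1 or not np.all(np.isfinite(R)):
            raise ValueError("R must be a finite vector")
        object.__setattr__(self, "R", R)


def successor_features(sm: SuccessorMatrix, f: np.ndarray) -> np.ndarray:
    """psi(s) = M f(s)."""
    f = np.asarray(f, dtype=float)
    if f.shape[-1] != sm.n:
        raise ValueError(f"feature dimension {f.shape[-1]} != {sm.n}")
    return f @ sm.M.T


def td_update(sm: SuccessorMatrix, f_t: np.ndarray, f_next: np.ndarray) -> SuccessorMatrix:
    """One TD step of the successor matrix for the transition f_t -> f_next."""
    f_t = np.asarray(f_t, dtype=float)
    f_next = np.asarray(f_next, dtype=float)
    if f_t.shape != (sm.n,) or f_next.shape != (sm.n,):
        raise ValueError("feature dimension mismatch")
    delta = f_t + sm.gamma * (sm.M @ f_next) - sm.M @ f_t
    M = sm.M + sm.alpha_M * np.outer(delta, f_t)
    return replace(sm, M=M, updates=sm.updates + 1)


def reward_update(
    rw: RewardWeights,
    psi_t: np.ndarray,
    psi_next: np.ndarray,
    reward_t: float,
    gamma: float,
) -> RewardWeights:
    """One TD step of the reward weights from the observed reward."""
    psi_t = np.asarray(psi_t, dtype=float)
    psi_next = np.asarray(psi_next, dtype=float)
    if psi_t.shape != rw.R.shape or psi_next.shape != rw.R.shape:
        raise ValueError("dimension mismatch")
    delta = reward_t + gamma * (psi_next @ rw.R) - psi_t @ rw.R
    return replace(rw, R=rw.R + rw.alpha_R * psi_t * delta)


def value(psi: np.ndarray, rw: RewardWeights) -> float:
    """V(s) = psi(s)^T R."""
    psi = np.asarray(psi, dtype=float)
    if psi.shape != rw.R.shape:
        raise ValueError("dimension mismatch")
    return float(psi @ rw.R)


def learn_sr(
    fmap: FeatureMap,
    traj: Trajectory,
    *,
    gamma: float = 0.99,
    alpha_M: float = 0.01,
    M0: SuccessorMatrix | None = None,
) -> SuccessorMatrix:
    """Run the TD update over every consecutive pair of trajectory samples.

    Feature vectors come from the precomputed bin grid (containing-bin
    lookup).  Learning starts from M0 when given — the continual-learning
    protocol for environmental manipulations — otherwise from the identity.
    The loop is vectorised per step only; the sequence order matters (the
    SR is policy dependent).
    """
    n = fmap.n
    sm = M0 if M0 is not None else SuccessorMatrix.identity(n, gamma=gamma, alpha_M=alpha_M)
    if sm.n != n:
        raise ValueError("M0 dimension does not match the feature map")
    if len(traj) <= 1:
        return sm
    feats = fmap.rates_at(traj.x, traj.y)  # (T, n)
    M = sm.M.copy()
    g = sm.gamma
    a = sm.alpha_M
    f_t = feats[0]
    psi_t = M @ f_t
    for k in range(1, feats.shape[0]):
        f_next = feats[k]
        psi_next = M @ f_next
        delta = f_t + g * psi_next - psi_t
        M += a * np.outer(delta, f_t)
        f_t = f_next
        # psi under the updated M (exact, one extra matvec)
        psi_t = M @ f_t
    return replace(sm, M=M, updates=sm.updates + feats.shape[0] - 1)
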