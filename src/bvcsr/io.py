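"""Plain-text persistence: matrices with JSON sidecars, trajectories as CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .motion import Trajectory
from .sr import SuccessorMatrix


def save_matrix(path: str | Path, M: np.ndarray, meta: dict | None = None) -> None:
    """Dense matrix as whitespace-delimited text plus a .json sidecar."""
    path = Path(path)
    np.savetxt(path, np.asarray(M))
    sidecar = dict(meta or {})
    sidecar["shape"] = list(np.shape(M))
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1, default=float))


def load_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    M = np.loadtxt(path)
    side = path.with_suffix(path.suffix + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return M, meta


def save_successor(path: str | Path, sm: SuccessorMatrix, extra: dict | None = None) -> None:
    meta = {"gamma": sm.gamma, "alpha_M": sm.alpha_M, "updates": sm.updates}
    meta.update(extra or {})
    save_matrix(path, sm.M, meta)


def load_successor(path: str | Path) -> SuccessorMatrix:
    M, meta = load_matrix(path)
    return SuccessorMatrix(
        M=M,
        gamma=float(meta.get("gamma", 0.99)),
        alpha_M=float(meta.get("alpha_M", 0.01)),
        updates=int(meta.get("updates", 0)),
    )


def save_trajectory(path: str | Path, traj: Trajectory) -> None:
    traj.to_dataframe().to_csv(path, index=False)


def load_trajectory(path: str | Path) -> Trajectory:
    return Trajectory.from_dataframe(pd.read_csv(path))
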