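"""Trajectory containers and HDF5 dataset I/O.

A :class:`TrajectorySet` holds uniformly sampled multivariate time series as
a single float32 array of shape ``(n_traj, n_steps, n_features)``; image
frames are stored flattened with the original frame shape kept as metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np


@dataclass
class TrajectorySet:
    """Uniformly sampled trajectories in ambient space.

    Parameters
    ----------
    data
        Array ``(n_traj, n_steps, n_features)``, float32.
    dt
        Time between consecutive samples, in the data's own time units.
    frame_shape
        If frames are images, their unflattened shape, e.g. ``(28, 28)``.
    meta
        Free-form JSON-serializable provenance (generator config etc.).
    """

    data: np.ndarray
    dt: float = 1.0
    frame_shape: tuple[int, ...] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(
                f"TrajectorySet data must be (n_traj, n_steps, n_features); "
                f"got ndim={self.data.ndim}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.frame_shape is not None:
            self.frame_shape = tuple(int(s) for s in self.frame_shape)
            if int(np.prod(self.frame_shape)) != self.data.shape[2]:
                raise ValueError("frame_shape does not match feature count")

    @property
    def n_traj(self) -> int:
        return self.data.shape[0]

    @property
    def n_steps(self) -> int:
        return self.data.shape[1]

    @property
    def n_features(self) -> int:
        return self.data.shape[2]

    def frames(self) -> np.ndarray:
        """All frames stacked: (n_traj * n_steps, n_features)."""
        return self.data.reshape(-1, self.n_features)


def write_dataset(ts: TrajectorySet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ts.data.astype(np.float32))
        f.create_dataset("dt", data=float(ts.dt))
        if ts.frame_shape is not None:
            f.create_dataset("frame_shape", data=np.asarray(ts.frame_shape, dtype=np.int64))
        f.create_dataset("meta", data=json.dumps(ts.meta))


def read_dataset(path) -> TrajectorySet:
    with h5py.File(path, "r") as f:
        for key in ("data", "dt"):
            if key not in f:
                raise KeyError(f"dataset file missing required key '{key}'")
        data = f["data"][()]
        if data.ndim != 3:
            raise ValueError("'data' must be a 3-D (n_traj, n_steps, n_features) array")
        dt = float(f["dt"][()])
        frame_shape = tuple(f["frame_shape"][()]) if "frame_shape" in f else None
        meta = json.loads(f["meta"][()]) if "meta" in f else {}
    return TrajectorySet(data=data, dt=dt, frame_shape=frame_shape, meta=meta)
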