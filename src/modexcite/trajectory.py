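"""Trajectory container and flat-file serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Ordered coordinate frames with a fixed inter-frame time step.

    ``frames`` has shape (n_frames, n_atoms, 3) in angstrom; ``dt`` is the
    time between stored frames in ps.
    """

    frames: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("need at least one frame")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def __getitem__(self, i) -> np.ndarray:
        return self.frames[i]

    def concat(self, other: "Trajectory") -> "Trajectory":
        if other.n_atoms != self.n_atoms:
            raise ValueError("atom count mismatch")
        return Trajectory(np.concatenate([self.frames, other.frames]), self.dt)

    def save(self, path) -> None:
        """Write frames as a raw float64 array plus a JSON sidecar."""
        path = Path(path)
        self.frames.astype("<f8").tofile(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "n_frames": int(self.n_frames),
                    "n_atoms": int(self.n_atoms),
                    "dt_ps": float(self.dt),
                    "dtype": "<f8",
                }
            )
        )

    @classmethod
    def load(cls, path) -> "Trajectory":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        raw = np.fromfile(path, dtype=meta["dtype"])
        frames = raw.reshape(meta["n_frames"], meta["n_atoms"], 3)
        return cls(frames, meta["dt_ps"])
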