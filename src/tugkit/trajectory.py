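"""The body-centroid trajectory — the pivot data structure of the method.

Every downstream stage (activity decoding, event detection, gait
parameters) consumes a :class:`CentroidTrajectory`: a time series of 3-D
body-centroid positions in a fixed world frame, in millimetres.  Axes:
``x`` lateral, ``y`` vertical (height above the floor), ``z`` range from
the camera plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CentroidTrajectory:
    """Time series of 3-D centroid samples.

    Parameters
    ----------
    t : array of float
        Timestamps in seconds, strictly increasing, length >= 2.
    x, y, z : arrays of float
        World coordinates in mm (x lateral, y vertical above floor,
        z range).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        for name in ("x", "y", "z"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise ValueError(f"{name} and t must have the same length")
            object.__setattr__(self, name, arr)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if not np.all(np.isfinite(t)):
            raise ValueError("timestamps must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("bad timestamps")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def sampling_rate(self) -> float:
        """Mean sampling rate in Hz."""
        return (len(self) - 1) / self.duration

    def horizontal(self) -> np.ndarray:
        """(n, 2) array of horizontal (x, z) positions in mm."""
        return np.column_stack([self.x, self.z])

    def index_at(self, time: float) -> int:
        """Index of the sample closest to ``time``."""
        return int(np.argmin(np.abs(self.t - time)))

    def slice_time(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of samples with t0 <= t <= t1."""
        return (self.t >= t0) & (self.t <= t1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.x, "y": self.y, "z": self.z})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CentroidTrajectory":
        return cls(
            t=df["t"].to_numpy(float),
            x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float),
            z=df["z"].to_numpy(float),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CentroidTrajectory":
        return cls.from_frame(pd.read_csv(path))


def moving_average(values: np.ndarray, window_samples: int) -> np.ndarray:
    """Centred moving average with edge truncation (no phase shift).

    ``window_samples`` is rounded up to the nearest odd integer; edges
    average over the available part of the window so the output has the
    same length as the input.
    """
    values = np.asarray(values, dtype=float)
    w = max(1, int(window_samples))
    if w % 2 == 0:
        w += 1
    if w == 1 or values.size < 2:
        return values.copy()
    half = w // 2
    csum = np.cumsum(np.concatenate([[0.0], values]))
    n = values.size
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth_height(traj: CentroidTrajectory, window_s: float) -> np.ndarray:
    """Smoothed vertical trace (mm) at the trajectory's sampling rate."""
    w = int(round(window_s * traj.sampling_rate))
    return moving_average(traj.y, w)


def vertical_velocity(traj: CentroidTrajectory, window_s: float) -> np.ndarray:
    """Finite-difference velocity (mm/s) of the smoothed vertical trace."""
    return np.gradient(smooth_height(traj, window_s), traj.t)
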