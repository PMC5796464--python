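"""Depth-frame IO, background subtraction, silhouette and centroid.

Frames are 16-bit single-channel PNGs whose pixel value is the range in
millimetres (0 = invalid / sensor dropout).  A sidecar ``timestamps.csv``
(``filename,t``) carries per-frame times; without it, frames are assumed
uniformly sampled at the camera frame rate, ordered by filename.

The person is segmented by static background subtraction: a per-pixel
reference depth (median over person-free frames) with a fixed tolerance;
foreground pixels are grouped into 4-connected components and the
largest sufficiently big component is the silhouette.  The body centroid
is the unweighted mean of all silhouette pixels back-projected to 3-D
through the pinhole model and expressed in the world frame (x lateral,
y height above floor, z range).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .config import CameraIntrinsics
from .trajectory import CentroidTrajectory


@dataclass(frozen=True)
class DepthSequence:
    """Timestamped stack of depth frames (mm), shape (n, H, W)."""

    frames: np.ndarray
    timestamps: np.ndarray
    camera: CameraIntrinsics

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        ts = np.asarray(self.timestamps, dtype=float)
        if frames.ndim != 3 or frames.shape[0] == 0:
            raise ValueError("no frames")
        if ts.shape != (frames.shape[0],):
            raise ValueError("one timestamp per frame required")
        if not np.all(np.isfinite(ts)):
            raise ValueError("bad timestamps")
        if ts.size > 1 and np.any(np.diff(ts) <= 0):
            raise ValueError("bad timestamps")
        if np.any(frames < 0):
            raise ValueError("negative depth")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "timestamps", ts)

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class BackgroundModel:
    """Per-pixel reference depth (mm) with a scalar tolerance (mm)."""

    reference: np.ndarray
    tolerance_mm: float

    def __post_init__(self) -> None:
        if self.tolerance_mm <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class Silhouette:
    """Pixels classified as the person in one frame."""

    timestamp: float
    rows: np.ndarray
    cols: np.ndarray
    depths: np.ndarray

    def __len__(self) -> int:
        return int(self.rows.size)


def load_depth_sequence(
    path: str | Path, camera: CameraIntrinsics | None = None
) -> DepthSequence:
    """Load a directory of 16-bit PNG depth frames.

    Timestamps come from a ``timestamps.csv`` sidecar (``filename,t``);
    if absent, frames are ordered lexicographically by filename and
    stamped uniformly at ``camera.frame_rate``.
    """
    camera = camera or CameraIntrinsics()
    path = Path(path)
    pngs = sorted(path.glob("*.png"))
    if not pngs:
        raise FileNotFoundError(f"no frames in {path}")
    sidecar = path / "timestamps.csv"
    if sidecar.exists():
        with open(sidecar, newline="") as fh:
            rows = list(csv.DictReader(fh))
        names = [r["filename"] for r in rows]
        times = np.array([float(r["t"]) for r in rows])
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("bad timestamps")
        files = [path / n for n in names]
    else:
        files = pngs
        times = np.arange(len(files)) / camera.frame_rate

    frames = []
    shape = None
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim != 2:
            raise ValueError(f"{f.name}: not single-channel")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError("shape mismatch")
        frames.append(img.astype(np.uint16))
    return DepthSequence(np.stack(frames), times, camera)


def write_depth_sequence(seq: DepthSequence, path: str | Path) -> None:
    """Write frames as 16-bit PNGs plus the timestamps sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    names = []
    for i, frame in enumerate(seq.frames):
        name = f"frame_{i:06d}.png"
        iio.imwrite(path / name, np.clip(frame, 0, 65535).astype(np.uint16))
        names.append(name)
    with open(path / "timestamps.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "t"])
        for name, t in zip(names, seq.timestamps):
            w.writerow([name, repr(float(t))])


def build_background(
    frames: DepthSequence | np.ndarray, tolerance_mm: float = 80.0
) -> BackgroundModel:
    """Static background: per-pixel median depth over person-free frames."""
    stack = frames.frames if isinstance(frames, DepthSequence) else np.asarray(frames)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] == 0:
        raise ValueError("no background frames")
    return BackgroundModel(np.median(stack.astype(float), axis=0), tolerance_mm)


# 4-connectivity
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def extract_silhouette(
    frame: np.ndarray,
    bg: BackgroundModel,
    min_blob_px: int = 50,
    timestamp: float = 0.0,
) -> Silhouette:
    """Largest 4-connected foreground component of one frame.

    Foreground = valid pixels (depth > 0) deviating from the background
    reference by more than the tolerance.  Components smaller than
    ``min_blob_px`` are discarded; an empty silhouette is a legal result
    (person absent).
    """
    frame = np.asarray(frame)
    if frame.shape != bg.reference.shape:
        raise ValueError("shape mismatch")
    fg = (frame > 0) & (np.abs(frame.astype(float) - bg.reference) > bg.tolerance_mm)
    labels, n = ndimage.label(fg, structure=_STRUCT4)
    empty = Silhouette(timestamp, np.array([], int), np.array([], int), np.array([], float))
    if n == 0:
        return empty
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_blob_px:
        return empty
    rows, cols = np.nonzero(labels == best)
    return Silhouette(timestamp, rows, cols, frame[rows, cols].astype(float))


def back_project(
    rows: np.ndarray, cols: np.ndarray, depths: np.ndarray, camera: CameraIntrinsics
) -> np.ndarray:
    """Pixel (row, col, depth mm) -> world (x, y, z) mm, zero camera tilt.

    x = (col - cx) * depth / fx (lateral),
    y = sensor_height - (row - cy) * depth / fy (height above floor),
    z = depth (range).
    """
    d = np.asarray(depths, dtype=float)
    x = (np.asarray(cols) - camera.cx) * d / camera.fx
    y = camera.sensor_height_mm - (np.asarray(rows) - camera.cy) * d / camera.fy
    return np.column_stack([x, y, d])


def compute_centroid(sil: Silhouette, camera: CameraIntrinsics) -> np.ndarray:
    """Unweighted mean 3-D position of all silhouette points (mm).

    Returns ``[x, y, z]``; raises if the silhouette is empty.
    """
    if len(sil) == 0:
        raise ValueError("no person")
    pts = back_project(sil.rows, sil.cols, sil.depths, camera)
    return pts.mean(axis=0)


def extract_trajectory(
    seq: DepthSequence,
    bg: BackgroundModel | None = None,
    min_blob_px: int = 50,
    n_background_frames: int = 0,
) -> CentroidTrajectory:
    """Run background subtraction + centroid over a whole sequence.

    If no background model is given, the first ``n_background_frames``
    frames (default: a built-in guess of 5) are assumed person-free and
    used to build one.  Frames with an empty silhouette are skipped.
    """
    if bg is None:
        k = n_background_frames or min(5, len(seq))
        bg = build_background(seq.frames[:k])
    ts, cents = [], []
    for frame, t in zip(seq.frames, seq.timestamps):
        sil = extract_silhouette(frame, bg, min_blob_px, timestamp=float(t))
        if len(sil) == 0:
            continue
        cents.append(compute_centroid(sil, seq.camera))
        ts.append(float(t))
    if len(ts) < 2:
        raise ValueError("no person detected in sequence")
    cents_arr = np.asarray(cents)
    return CentroidTrajectory(
        t=np.asarray(ts), x=cents_arr[:, 0], y=cents_arr[:, 1], z=cents_arr[:, 2]
    )
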