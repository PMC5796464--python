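"""Camera geometry and pipeline configuration.

The depth sensor is modelled as an ideal pinhole camera mounted level
(zero tilt) at a known height above the floor.  All distances are in
millimetres, all times in seconds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics of the depth sensor plus its mounting height.

    Defaults are Kinect-v2-like: a 512x424 depth image with focal
    lengths of 365 px and the principal point at the image centre.
    ``sensor_height_mm`` is the height of the optical centre above the
    floor; the world vertical axis is recovered from it assuming zero
    camera tilt.
    """

    fx: float = 365.0
    fy: float = 365.0
    cx: float = 256.0
    cy: float = 212.0
    width: int = 512
    height: int = 424
    sensor_height_mm: float = 1000.0
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point outside the image")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CameraIntrinsics":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable constants of the segmentation stage.

    * ``smoothing_window_s`` — centred moving-average window applied to
      the vertical centroid trace before velocity estimation.
    * ``turn_fraction`` — the person's position furthest from the chair
      defines the turn; all contiguous samples beyond this fraction of
      the maximum chair distance form the turn window.
    * ``min_stop_duration_s`` — a standing run during the walk shorter
      than this is not reported as a stop (hesitation).
    * ``standing_height_percentile`` — the standing height used to
      normalise the vertical trace is this percentile of the height
      series (robust to noise spikes).
    """

    smoothing_window_s: float = 0.25
    turn_fraction: float = 0.95
    min_stop_duration_s: float = 0.5
    standing_height_percentile: float = 95.0
    chair_position: tuple[float, float] | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SegmentationConfig":
        d = json.loads(Path(path).read_text())
        if d.get("chair_position") is not None:
            d["chair_position"] = tuple(d["chair_position"])
        return cls(**d)


@dataclass(frozen=True)
class GaitConfig:
    """Constants of the step-detection stage (mm / s)."""

    min_prominence_mm: float = 5.0
    edge_margin_s: float = 0.12
    smoothing_window_s: float = 0.25


DEFAULT_CAMERA = CameraIntrinsics()
DEFAULT_SEGMENTATION = SegmentationConfig()
DEFAULT_GAIT = GaitConfig()
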