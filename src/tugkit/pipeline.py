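"""End-to-end convenience wrappers: depth frames -> trajectory -> 21 parameters."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GaitConfig, SegmentationConfig
from .depthio import DepthSequence, extract_trajectory
from .gait import StepSeries, TUGParameters, compute_parameters, detect_steps
from .segmentation import ActivityHMM, EventSet, detect_events, decode_activities
from .trajectory import CentroidTrajectory


@dataclass(frozen=True)
class TUGAnalysis:
    """Everything the pipeline derives from one trial."""

    trajectory: CentroidTrajectory
    labels: np.ndarray
    events: EventSet
    steps: StepSeries
    parameters: TUGParameters


def analyze_trajectory(
    traj: CentroidTrajectory,
    hmm: ActivityHMM | None = None,
    seg_config: SegmentationConfig | None = None,
    gait_config: GaitConfig | None = None,
) -> TUGAnalysis:
    """Segment a centroid trajectory and compute the 21 TUG parameters."""
    labels = decode_activities(traj, hmm, seg_config)
    events = detect_events(labels, traj, seg_config)
    steps = detect_steps(traj, events, config=gait_config)
    params = compute_parameters(traj, events, steps, gait_config)
    return TUGAnalysis(traj, labels, events, steps, params)


def analyze_depth_sequence(
    seq: DepthSequence,
    n_background_frames: int = 5,
    min_blob_px: int = 50,
    hmm: ActivityHMM | None = None,
    seg_config: SegmentationConfig | None = None,
    gait_config: GaitConfig | None = None,
) -> TUGAnalysis:
    """Full path from raw depth frames: silhouette -> centroid -> parameters.

    The first ``n_background_frames`` frames must be person-free; they
    seed the static background model.
    """
    traj = extract_trajectory(
        seq, min_blob_px=min_blob_px, n_background_frames=n_background_frames
    )
    return analyze_trajectory(traj, hmm, seg_config, gait_config)
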