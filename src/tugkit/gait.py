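"""Step detection and the 21 TUG parameters.

Steps are read off the vertical centroid oscillation: during walking the
body centre bobs once per step, so each local maximum of the smoothed
height trace marks a step and one step is the interval between two
consecutive maxima.  Peaks are searched only inside the two walking
spans (chair -> turn and turn -> chair), with stop intervals excised,
and are never paired across the turn or across a stop.  Step length is
the horizontal distance between the 3-D centroid positions at two
consecutive peaks.

Parameter conventions (fixed for determinism, see the methods note):
coefficient-of-variation values use the population (1/n) standard
deviation and are reported in percent; cadence is the reciprocal of
step duration in steps/s; gait speed is the ratio of summed step
lengths to summed step durations in cm/s.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import GaitConfig
from .segmentation import EventSet
from .trajectory import CentroidTrajectory, moving_average

#: Canonical order of the 21 parameter columns.
PARAMETER_NAMES = (
    "total_duration",
    "time_to_get_up",
    "speed_to_get_up",
    "time_to_sit_down",
    "speed_to_sit_down",
    "time_to_walk",
    "n_stops",
    "width_of_turn",
    "time_of_turn",
    "greatest_width_walk",
    "n_steps",
    "mean_step_length",
    "median_step_length",
    "cv_step_length",
    "mean_step_duration",
    "median_step_duration",
    "cv_step_duration",
    "mean_cadence",
    "median_cadence",
    "cv_cadence",
    "gait_speed",
)


@dataclass(frozen=True)
class StepSeries:
    """Detected step peaks and the per-step lengths/durations.

    ``peak_times`` in s, ``peak_positions`` (n, 3) in mm,
    ``step_lengths`` in cm, ``step_durations`` in s.  Peaks in different
    spans are never paired, so there is one fewer step than peaks per
    span, not overall; ``span_of_peak`` records the span index.
    """

    peak_times: np.ndarray
    peak_positions: np.ndarray
    step_lengths: np.ndarray
    step_durations: np.ndarray
    span_of_peak: np.ndarray

    def __post_init__(self) -> None:
        if len(self.step_lengths) != len(self.step_durations):
            raise ValueError("lengths and durations must align")
        if np.any(np.asarray(self.step_durations) <= 0):
            raise ValueError("step durations must be positive")

    @property
    def n_steps(self) -> int:
        return int(len(self.step_lengths))


def _walking_subspans(events: EventSet) -> list[tuple[float, float]]:
    """Walking intervals: forward and return spans minus stop intervals."""
    spans = [(events.start_walk, events.start_turn), (events.end_turn, events.start_sit)]
    out = []
    for lo, hi in spans:
        cur = lo
        for s0, s1 in events.stops:
            if s0 >= hi or s1 <= lo:
                continue
            if s0 > cur:
                out.append((cur, s0))
            cur = max(cur, s1)
        if hi > cur:
            out.append((cur, hi))
    return [(lo, hi) for lo, hi in out if hi > lo]


def detect_steps(
    traj: CentroidTrajectory,
    events: EventSet,
    min_prominence_mm: float | None = None,
    config: GaitConfig | None = None,
) -> StepSeries:
    """Local maxima of the smoothed height inside the walking sub-spans.

    Peaks need a prominence of at least ``min_prominence_mm`` and at
    least 0.3 s separation (no plausible gait is faster); peaks within
    ``config.edge_margin_s`` of a sub-span boundary are discarded as
    edge artifacts.  Consecutive peaks of the same sub-span form steps.
    """
    config = config or GaitConfig()
    if min_prominence_mm is None:
        min_prominence_mm = config.min_prominence_mm
    rate = traj.sampling_rate
    w = int(round(config.smoothing_window_s * rate))
    h = moving_average(traj.y, w)
    xs = moving_average(traj.x, w)
    zs = moving_average(traj.z, w)
    min_dist = max(1, int(round(0.3 * rate)))

    peak_t, peak_pos, peak_span = [], [], []
    lengths, durations = [], []
    for k, (lo, hi) in enumerate(_walking_subspans(events)):
        mask = traj.slice_time(lo, hi)
        idx = np.flatnonzero(mask)
        if idx.size < 3:
            continue
        seg = h[idx]
        peaks, _ = find_peaks(seg, prominence=min_prominence_mm, distance=min_dist)
        keep = [
            p
            for p in peaks
            if traj.t[idx[p]] - lo >= config.edge_margin_s
            and hi - traj.t[idx[p]] >= config.edge_margin_s
        ]
        prev = None
        for p in keep:
            i = idx[p]
            tp = float(traj.t[i])
            pos = np.array([xs[i], traj.y[i], zs[i]])
            peak_t.append(tp)
            peak_pos.append(pos)
            peak_span.append(k)
            if prev is not None:
                dt = tp - prev[0]
                dxz = np.hypot(pos[0] - prev[1][0], pos[2] - prev[1][2])
                durations.append(dt)
                lengths.append(dxz / 10.0)  # mm -> cm
            prev = (tp, pos)

    if not lengths:
        raise ValueError("no steps detected")
    return StepSeries(
        peak_times=np.asarray(peak_t),
        peak_positions=np.asarray(peak_pos),
        step_lengths=np.asarray(lengths),
        step_durations=np.asarray(durations),
        span_of_peak=np.asarray(peak_span),
    )


def _cv_percent(values: np.ndarray) -> float:
    """Population-SD coefficient of variation, in percent."""
    m = float(np.mean(values))
    if m == 0:
        return float("nan")
    return 100.0 * float(np.std(values)) / abs(m)


@dataclass(frozen=True)
class TUGParameters:
    """The 21 parameters of one TUG trial (units in field names' docs).

    Times in s, vertical speeds in mm/s (sit-down speed negative),
    widths and step lengths in cm, cadence in steps/s, gait speed in
    cm/s, CVs in percent.
    """

    total_duration: float
    time_to_get_up: float
    speed_to_get_up: float
    time_to_sit_down: float
    speed_to_sit_down: float
    time_to_walk: float
    n_stops: int
    width_of_turn: float
    time_of_turn: float
    greatest_width_walk: float
    n_steps: int
    mean_step_length: float
    median_step_length: float
    cv_step_length: float
    mean_step_duration: float
    median_step_duration: float
    cv_step_duration: float
    mean_cadence: float
    median_cadence: float
    cv_cadence: float
    gait_speed: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_series(self) -> pd.Series:
        return pd.Series(self.to_dict())[list(PARAMETER_NAMES)]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def compute_parameters(
    traj: CentroidTrajectory,
    events: EventSet,
    steps: StepSeries,
    config: GaitConfig | None = None,
) -> TUGParameters:
    """Assemble the 21 parameters from trajectory, events and steps.

    Phase times are direct event differences; walking time excludes
    stop intervals.  Get-up / sit-down speeds are the extreme values of
    the smoothed vertical velocity inside the respective phases.  The
    turn width is the horizontal distance between the positions at the
    turn boundaries; the greatest walk width is the directed Hausdorff
    (max-of-min) horizontal distance from the forward-walk path to the
    return-walk path.
    """
    config = config or GaitConfig()
    w = int(round(config.smoothing_window_s * traj.sampling_rate))
    h = moving_average(traj.y, w)
    vel = moving_average(np.gradient(h, traj.t), w)
    xs = moving_average(traj.x, w)
    zs = moving_average(traj.z, w)

    up_mask = traj.slice_time(events.start_move, events.start_walk)
    down_mask = traj.slice_time(events.start_sit, events.end_sit)
    if not up_mask.any() or not down_mask.any():
        raise ValueError("incomplete segmentation")
    speed_up = float(np.max(vel[up_mask]))
    speed_down = float(np.min(vel[down_mask]))

    i_st = traj.index_at(events.start_turn)
    i_et = traj.index_at(events.end_turn)
    width_turn = float(np.hypot(xs[i_et] - xs[i_st], zs[i_et] - zs[i_st])) / 10.0

    fwd = traj.slice_time(events.start_walk, events.start_turn)
    ret = traj.slice_time(events.end_turn, events.start_sit)
    if fwd.any() and ret.any():
        fp = np.column_stack([xs[fwd], zs[fwd]])
        rp = np.column_stack([xs[ret], zs[ret]])
        dists = np.sqrt(((fp[:, None, :] - rp[None, :, :]) ** 2).sum(axis=2))
        greatest_width = float(dists.min(axis=1).max()) / 10.0
    else:
        greatest_width = float("nan")

    time_to_walk = (
        (events.start_turn - events.start_walk)
        + (events.start_sit - events.end_turn)
        - events.stop_time
    )

    lengths = steps.step_lengths
    durations = steps.step_durations
    cadences = 1.0 / durations

    return TUGParameters(
        total_duration=events.end_sit - events.start_move,
        time_to_get_up=events.start_walk - events.start_move,
        speed_to_get_up=speed_up,
        time_to_sit_down=events.end_sit - events.start_sit,
        speed_to_sit_down=speed_down,
        time_to_walk=time_to_walk,
        n_stops=len(events.stops),
        width_of_turn=width_turn,
        time_of_turn=events.end_turn - events.start_turn,
        greatest_width_walk=greatest_width,
        n_steps=steps.n_steps,
        mean_step_length=float(np.mean(lengths)),
        median_step_length=float(np.median(lengths)),
        cv_step_length=_cv_percent(lengths),
        mean_step_duration=float(np.mean(durations)),
        median_step_duration=float(np.median(durations)),
        cv_step_duration=_cv_percent(durations),
        mean_cadence=float(np.mean(cadences)),
        median_cadence=float(np.median(cadences)),
        cv_cadence=_cv_percent(cadences),
        gait_speed=float(np.sum(lengths) / np.sum(durations)),
    )


def parameters_to_frame(params: list[TUGParameters]) -> pd.DataFrame:
    return pd.DataFrame([p.to_dict() for p in params])[list(PARAMETER_NAMES)]
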