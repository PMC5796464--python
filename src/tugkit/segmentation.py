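"""Activity decoding and TUG event detection on the centroid trajectory.

The vertical centroid trace is summarised per sample by two features —
height relative to the person's standing height, and vertical velocity —
and decoded into five activities (sitting, transition up, standing,
walking, transition down) with a fixed-parameter Gaussian hidden Markov
model.  The six test events plus optional stop intervals are then read
off the label runs:

* ``start_move``  — first non-sitting sample after the initial sitting run;
* ``start_walk``  — first sample labelled walking;
* ``start_sit``   — first sample after the last walking run;
* ``end_sit``     — last sample before the final sitting run;
* ``start_turn`` / ``end_turn`` — from the chair-distance profile: the
  maximal contiguous window around the farthest point where the distance
  stays above a fixed fraction (default 95%) of its maximum;
* stops — standing runs strictly inside the walking span, at least
  ``min_stop_duration`` long and disjoint from the turn window.

The HMM is hand-specified, not trained: emission means/variances encode
simple biomechanical priors (sitting at ~60% of standing height, sizable
vertical speed during postural transitions, oscillating vertical speed
during gait) and the transition matrix forbids implausible jumps such as
sitting -> walking without an intermediate transition state.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .config import SegmentationConfig
from .trajectory import CentroidTrajectory, moving_average, smooth_height

logger = logging.getLogger(__name__)


class ActivityLabel(IntEnum):
    """Closed set of decoded activities, in the fixed tie-break order."""

    SITTING = 0
    TRANSITION_UP = 1
    STANDING = 2
    WALKING = 3
    TRANSITION_DOWN = 4


N_STATES = len(ActivityLabel)


@dataclass(frozen=True)
class ActivityHMM:
    """Fixed-parameter HMM over (relative height, vertical velocity).

    ``means`` and ``stds`` are (5, 2) arrays over the observation pair;
    relative height is unitless (1.0 = standing), velocity in mm/s.
    Rows follow the :class:`ActivityLabel` order.
    """

    startprob: np.ndarray = field(
        default_factory=lambda: np.array([0.96, 0.01, 0.01, 0.01, 0.01])
    )
    transmat: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                # sit    t_up   stand  walk   t_down
                [0.990, 0.010, 0.000, 0.000, 0.000],  # sitting
                [0.000, 0.930, 0.050, 0.020, 0.000],  # transition_up
                [0.000, 0.000, 0.900, 0.050, 0.050],  # standing
                [0.000, 0.000, 0.055, 0.925, 0.020],  # walking
                [0.050, 0.000, 0.000, 0.000, 0.950],  # transition_down
            ]
        )
    )
    means: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.59, 0.0],  # sitting
                [0.80, 280.0],  # transition_up
                [0.975, 0.0],  # standing (plateau sits at an oscillation trough)
                [0.99, 0.0],  # walking (baseline just below the calibrated peak)
                [0.85, -240.0],  # transition_down
            ]
        )
    )
    stds: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.05, 20.0],  # sitting: near-constant low posture
                [0.09, 180.0],  # transition_up: rising fast
                [0.02, 15.0],  # standing: erect and still
                [0.015, 36.0],  # walking: erect, oscillating speed
                [0.15, 160.0],  # transition_down: descending, broader posture band
            ]
        )
    )

    def __post_init__(self) -> None:
        t = np.asarray(self.transmat, float)
        if t.shape != (N_STATES, N_STATES):
            raise ValueError("transition matrix must be 5x5")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if np.any(np.asarray(self.stds) <= 0):
            raise ValueError("emission stds must be positive")

    def to_hmmlearn(self) -> GaussianHMM:
        model = GaussianHMM(n_components=N_STATES, covariance_type="diag", init_params="")
        model.startprob_ = np.asarray(self.startprob, float)
        model.transmat_ = np.asarray(self.transmat, float)
        model.means_ = np.asarray(self.means, float)
        model.covars_ = np.asarray(self.stds, float) ** 2
        model.n_features = 2
        return model


@dataclass(frozen=True)
class EventSet:
    """Timestamps (s) of the six TUG events plus stop intervals."""

    start_move: float
    start_walk: float
    start_turn: float
    end_turn: float
    start_sit: float
    end_sit: float
    stops: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        seq = [
            self.start_move,
            self.start_walk,
            self.start_turn,
            self.end_turn,
            self.start_sit,
            self.end_sit,
        ]
        if any(not np.isfinite(v) for v in seq):
            raise ValueError("events must be finite")
        if any(b < a - 1e-12 for a, b in zip(seq, seq[1:])):
            raise ValueError("events out of order")
        prev_end = None
        for t0, t1 in self.stops:
            if t1 <= t0:
                raise ValueError("empty stop interval")
            if t0 < self.start_walk - 1e-12 or t1 > self.start_sit + 1e-12:
                raise ValueError("stop outside walking span")
            if t1 > self.start_turn + 1e-12 and t0 < self.end_turn - 1e-12:
                raise ValueError("stop overlaps turn")
            if prev_end is not None and t0 < prev_end:
                raise ValueError("stops must be ordered and disjoint")
            prev_end = t1

    @property
    def stop_time(self) -> float:
        return float(sum(t1 - t0 for t0, t1 in self.stops))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stops"] = [list(s) for s in self.stops]
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "EventSet":
        d = dict(d)
        d["stops"] = tuple(tuple(s) for s in d.get("stops", ()))
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "EventSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def observation_features(
    traj: CentroidTrajectory, config: SegmentationConfig | None = None
) -> tuple[np.ndarray, float]:
    """(n, 2) observation matrix (relative height, vertical velocity).

    Height is smoothed by a centred moving average and normalised by the
    standing height (a high percentile of the smoothed series); velocity
    is the finite-difference derivative of the smoothed height, smoothed
    once more with the same window to suppress sensor noise.
    Returns the observations and the calibrated standing height (mm).
    """
    config = config or SegmentationConfig()
    w = int(round(config.smoothing_window_s * traj.sampling_rate))
    if len(traj) < max(2, w):
        raise ValueError("trajectory too short")
    h = moving_average(traj.y, w)
    standing = float(np.percentile(h, config.standing_height_percentile))
    if standing <= 0:
        raise ValueError("non-positive standing height")
    v = moving_average(np.gradient(h, traj.t), w)
    return np.column_stack([h / standing, v]), standing


def decode_activities(
    traj: CentroidTrajectory,
    hmm: ActivityHMM | None = None,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Most-probable activity path (Viterbi), one label per sample."""
    hmm = hmm or ActivityHMM()
    obs, _ = observation_features(traj, config)
    states = hmm.to_hmmlearn().predict(obs)
    return states.astype(int)


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (label, start_idx, end_idx_inclusive)."""
    labels = np.asarray(labels)
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change - 1, [labels.size - 1]])
    return [(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def detect_turn(
    traj: CentroidTrajectory,
    chair_position: tuple[float, float],
    fraction: float = 0.95,
    smoothing_window_s: float = 0.25,
) -> tuple[float, float]:
    """Turn window from the chair-distance profile.

    The farthest point from the chair anchors the turn; the window is
    the maximal contiguous interval containing it where the horizontal
    chair distance stays at or above ``fraction`` of the maximum.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    w = int(round(smoothing_window_s * traj.sampling_rate))
    x = moving_average(traj.x, w)
    z = moving_average(traj.z, w)
    d = np.hypot(x - chair_position[0], z - chair_position[1])
    i_max = int(np.argmax(d))
    d_max = d[i_max]
    if d_max < 1e-9:
        raise ValueError("no excursion")
    above = d >= fraction * d_max
    lo = i_max
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i_max
    while hi < d.size - 1 and above[hi + 1]:
        hi += 1
    return float(traj.t[lo]), float(traj.t[hi])


def estimate_chair_position(
    traj: CentroidTrajectory, labels: np.ndarray
) -> tuple[float, float]:
    """Horizontal centroid averaged over the initial sitting run."""
    runs = _runs(labels)
    if not runs or runs[0][0] != ActivityLabel.SITTING:
        # fall back to the first few samples
        k = max(2, int(0.5 * traj.sampling_rate))
        return float(np.mean(traj.x[:k])), float(np.mean(traj.z[:k]))
    _, s, e = runs[0]
    return float(np.mean(traj.x[s : e + 1])), float(np.mean(traj.z[s : e + 1]))


def detect_events(
    labels: np.ndarray,
    traj: CentroidTrajectory,
    config: SegmentationConfig | None = None,
) -> EventSet:
    """Locate the six TUG events and stop intervals from the label runs."""
    config = config or SegmentationConfig()
    labels = np.asarray(labels)
    if labels.shape != traj.t.shape:
        raise ValueError("labels must cover the trajectory")
    t = traj.t
    runs = _runs(labels)

    # start_move: first non-sitting sample after the initial sitting run
    if runs[0][0] == ActivityLabel.SITTING:
        if len(runs) < 2:
            raise ValueError("walk not found")
        start_move = float(t[runs[1][1]])
    else:
        start_move = float(t[0])

    walk_idx = np.flatnonzero(labels == ActivityLabel.WALKING)
    if walk_idx.size == 0:
        raise ValueError("walk not found")
    start_walk = float(t[walk_idx[0]])

    # start_sit: first sample after the last walking run
    last_walk = int(walk_idx[-1])
    if last_walk + 1 >= labels.size:
        raise ValueError("sit-down not found")
    start_sit = float(t[last_walk + 1])

    # end_sit: last sample before the final sitting run
    if runs[-1][0] != ActivityLabel.SITTING:
        raise ValueError("sit-down not found")
    end_sit = float(t[runs[-1][1] - 1]) if runs[-1][1] > 0 else float(t[0])

    chair = config.chair_position or estimate_chair_position(traj, labels)
    start_turn, end_turn = detect_turn(
        traj, chair, config.turn_fraction, config.smoothing_window_s
    )
    # the 95% window may spill over decoded non-walking samples; clip to
    # the walking span so the event ordering invariant holds
    clipped_lo = max(start_turn, start_walk)
    clipped_hi = min(end_turn, start_sit)
    if (clipped_lo, clipped_hi) != (start_turn, end_turn):
        logger.warning(
            "turn window [%0.3f, %0.3f] clipped to walking span", start_turn, end_turn
        )
        start_turn, end_turn = clipped_lo, min(max(clipped_hi, clipped_lo), start_sit)

    # stops: standing runs strictly inside the walking span, long enough,
    # and disjoint from the turn window
    stops = []
    for lab, s, e in runs:
        if lab != ActivityLabel.STANDING:
            continue
        t0, t1 = float(t[s]), float(t[e])
        if t0 <= start_walk or t1 >= start_sit:
            continue
        if t1 > start_turn and t0 < end_turn:  # overlaps the turn maneuver
            continue
        if t1 - t0 >= config.min_stop_duration_s:
            stops.append((t0, t1))

    return EventSet(
        start_move=start_move,
        start_walk=start_walk,
        start_turn=start_turn,
        end_turn=end_turn,
        start_sit=start_sit,
        end_sit=end_sit,
        stops=tuple(stops),
    )


def segment(
    traj: CentroidTrajectory,
    hmm: ActivityHMM | None = None,
    config: SegmentationConfig | None = None,
) -> tuple[np.ndarray, EventSet]:
    """Decode activities and detect events in one call."""
    labels = decode_activities(traj, hmm, config)
    return labels, detect_events(labels, traj, config)


def labels_to_frame(traj: CentroidTrajectory, labels: np.ndarray) -> pd.DataFrame:
    names = [ActivityLabel(int(v)).name.lower() for v in labels]
    return pd.DataFrame({"t": traj.t, "label": names})
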