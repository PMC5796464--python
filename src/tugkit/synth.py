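"""Synthetic TUG trials with exact ground truth.

The generator emulates the standard protocol: the person sits on a
chair, rises, walks ~3 m laterally in front of the depth sensor, turns
180 degrees around the floor mark, walks back on a parallel path and
sits down again.  The vertical centroid trace is piecewise: sitting
plateaus, smoothstep sit<->stand transitions, and a per-step sinusoidal
bob during gait.  Everything downstream of the generator can thus be
validated against analytically known events, steps and parameters.

Model choices that matter to the ground truth:

* The person walks a whole number of steps per direction: the forward
  distance is rounded up to ``N = ceil(walk_distance / step_length)``
  full steps (one turns *after* passing the mark).  Height peaks then
  fall half a step period away from every span boundary.
* Hesitation stops snap to step boundaries (oscillation troughs) — one
  stops after completing a step — so no height peak ever sits close to
  a stop edge either.
* The turn is a semicircular arc (radius = half the separation between
  the forward and return paths) bulging away from the chair.
* Ground-truth turn events follow the method's own definition — the
  window where the chair distance exceeds 95% of its maximum — applied
  in closed form to the noise-free path.  The physical arc boundaries
  are kept alongside for reference.
* Every walking span starts and ends at an oscillation trough (height
  ``stand_height - amplitude``, zero vertical velocity), and all
  standing plateaus (turn, stops) sit at that trough height, so the
  whole height trace is continuous with continuous velocity — no
  envelope tricks needed.  Sit-to-stand and stand-to-sit transitions
  run between the sitting height and the trough height.

All randomness (sensor noise) is drawn from a generator seeded by the
scenario, so trajectories are pure functions of (scenario, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CameraIntrinsics
from .depthio import DepthSequence
from .gait import PARAMETER_NAMES, TUGParameters
from .segmentation import EventSet
from .trajectory import CentroidTrajectory

logger = logging.getLogger(__name__)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


@dataclass(frozen=True)
class TUGScenario:
    """Parameters of one synthetic TUG trial (mm, s, Hz).

    ``stops`` are (onset, duration) pairs; the onset is walking time
    elapsed since start-walk, counting only moving time (the turn and
    earlier stops excluded), and is snapped to the nearest completed
    step.  ``chair_x``/``walk_z`` place the chair in the world frame of
    a sensor looking down +z from ~4 m; ``path_separation`` is the
    lateral offset between the forward and the return path.
    """

    sit_height: float = 600.0
    stand_height: float = 1000.0
    t_get_up: float = 1.5
    walk_distance: float = 3000.0
    gait_speed: float = 700.0
    step_frequency: float = 1.6
    step_oscillation_amplitude: float = 15.0
    turn_duration: float = 2.0
    t_sit_down: float = 1.5
    stops: tuple[tuple[float, float], ...] = ()
    noise_sd: float = 5.0
    frame_rate: float = 30.0
    seed: int = 0
    initial_sit_s: float = 2.0
    final_sit_s: float = 2.0
    chair_x: float = -1650.0
    walk_z: float = 3850.0
    path_separation: float = 300.0

    def __post_init__(self) -> None:
        if not (self.stand_height > self.sit_height > 0):
            raise ValueError("invalid scenario: need stand_height > sit_height > 0")
        for name in (
            "t_get_up",
            "walk_distance",
            "gait_speed",
            "step_frequency",
            "turn_duration",
            "t_sit_down",
            "frame_rate",
            "initial_sit_s",
            "final_sit_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"invalid scenario: {name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("invalid scenario: negative noise")
        D = self.span_moving_duration
        for onset, dur in self.stops:
            if dur <= 0:
                raise ValueError("invalid scenario: stop duration must be positive")
            c = self.snap_stop_onset(onset)
            if not (0.5 <= c <= 2 * D - 0.5) or abs(c - D) < 0.5:
                raise ValueError("invalid scenario: stop outside walk or at the turn")

    # -- derived geometry -------------------------------------------------
    @property
    def step_length(self) -> float:
        return self.gait_speed / self.step_frequency

    @property
    def n_steps_per_span(self) -> int:
        """Full steps per direction; one turns after passing the mark."""
        return math.ceil(self.walk_distance / self.step_length)

    @property
    def span_moving_duration(self) -> float:
        return self.n_steps_per_span / self.step_frequency

    @property
    def span_distance(self) -> float:
        return self.n_steps_per_span * self.step_length

    def snap_stop_onset(self, onset: float) -> float:
        """Snap a stop onset to the nearest completed step (trough)."""
        return round(onset * self.step_frequency) / self.step_frequency

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stops"] = [list(s) for s in self.stops]
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TUGScenario":
        d = json.loads(Path(path).read_text())
        d["stops"] = tuple(tuple(s) for s in d.get("stops", ()))
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic ground truth of a generated trial."""

    events: EventSet
    physical_turn: tuple[float, float]
    peak_times: np.ndarray
    step_lengths: np.ndarray
    step_durations: np.ndarray
    parameters: TUGParameters
    standing_height: float


class _Timeline:
    """Wall-clock layout of one scenario (all stops snapped)."""

    def __init__(self, scn: TUGScenario):
        self.scn = scn
        D = scn.span_moving_duration
        self.D = D
        # stop cuts in global moving time [0, 2D], sorted
        cuts = sorted((scn.snap_stop_onset(o), d) for o, d in scn.stops)
        self.cuts = cuts
        self.t_move = scn.initial_sit_s
        self.t_walk = self.t_move + scn.t_get_up
        self.turn_start = self.t_walk + D + sum(d for c, d in cuts if c < D)
        self.turn_end = self.turn_start + scn.turn_duration
        self.start_sit = self.turn_end + D + sum(d for c, d in cuts if c >= D)
        self.end_sit = self.start_sit + scn.t_sit_down
        self.total = self.end_sit + scn.final_sit_s

    def wall(self, tau: float) -> float:
        """Wall time of global moving time ``tau`` in [0, 2D]."""
        w = self.t_walk + tau + sum(d for c, d in self.cuts if c < tau)
        if tau > self.D:
            w += self.scn.turn_duration
        return w

    def stop_intervals(self) -> list[tuple[float, float]]:
        out = []
        for c, d in self.cuts:
            w0 = self.wall(c)
            out.append((w0, w0 + d))
        return out

def _turn_geometry(scn: TUGScenario) -> tuple[float, float, float]:
    """(d_max, d_star, g): max chair distance, 95% threshold, return-x offset."""
    NL = scn.span_distance
    r = scn.path_separation / 2.0
    theta = math.atan2(r, NL)  # farthest arc point from the chair
    d_max = math.hypot(NL + r * math.cos(theta), r * (1.0 + math.sin(theta)))
    d_star = 0.95 * d_max
    g = math.sqrt(d_star**2 - scn.path_separation**2)
    return d_max, d_star, g


def generate_trajectory(scn: TUGScenario) -> tuple[CentroidTrajectory, GroundTruth]:
    """Render one synthetic centroid trajectory and its ground truth."""
    tl = _Timeline(scn)
    rng = np.random.default_rng(scn.seed)
    n = int(math.floor(tl.total * scn.frame_rate)) + 1
    t = np.arange(n) / scn.frame_rate

    x = np.full(n, scn.chair_x)
    y = np.full(n, scn.sit_height)
    z = np.full(n, scn.walk_z)
    A = scn.step_oscillation_amplitude
    trough = scn.stand_height - A  # walking spans start/end here
    H = trough - scn.sit_height
    v = scn.gait_speed
    f = scn.step_frequency
    D = tl.D
    NL = scn.span_distance
    sep = scn.path_separation
    r = sep / 2.0
    z_ret = scn.walk_z + sep

    # rise
    m = (t >= tl.t_move) & (t < tl.t_walk)
    y[m] = scn.sit_height + H * _smoothstep((t[m] - tl.t_move) / scn.t_get_up)

    # walking spans (with stop plateaus)
    def fill_walk(span: int) -> None:
        lo_m, hi_m = (0.0, D) if span == 0 else (D, 2 * D)
        wall_lo = tl.wall(lo_m) if span == 0 else tl.turn_end
        cuts = [(c, d) for c, d in tl.cuts if lo_m < c < hi_m]
        # walking pieces between cuts
        cur_m = lo_m
        cur_w = wall_lo
        pieces = []
        for c, d in cuts:
            pieces.append((cur_w, cur_m, c))
            cur_w += (c - cur_m) + d
            cur_m = c
        pieces.append((cur_w, cur_m, hi_m))
        for w0, m0, m1 in pieces:
            mask = (t >= w0) & (t < w0 + (m1 - m0))
            tau = m0 + (t[mask] - w0)  # global moving time
            tau_loc = tau - lo_m
            y[mask] = scn.stand_height - A * np.cos(2 * np.pi * f * tau_loc)
            if span == 0:
                x[mask] = scn.chair_x + v * tau
                z[mask] = scn.walk_z
            else:
                x[mask] = scn.chair_x + NL - v * (tau - D)
                z[mask] = z_ret
        # stop plateaus (stops snap to troughs, so the join is smooth)
        for c, d in cuts:
            w0 = tl.wall(c)
            mask = (t >= w0) & (t < w0 + d)
            y[mask] = trough
            if span == 0:
                x[mask] = scn.chair_x + v * c
                z[mask] = scn.walk_z
            else:
                x[mask] = scn.chair_x + NL - v * (c - D)
                z[mask] = z_ret

    fill_walk(0)
    fill_walk(1)

    # turn arc
    m = (t >= tl.turn_start) & (t < tl.turn_end)
    theta = -np.pi / 2 + np.pi * (t[m] - tl.turn_start) / scn.turn_duration
    x[m] = scn.chair_x + NL + r * np.cos(theta)
    y[m] = trough
    z[m] = scn.walk_z + r + r * np.sin(theta)

    # descent and final sit
    m = t >= tl.start_sit
    x[m] = scn.chair_x
    z[m] = z_ret
    u = (t[m] - tl.start_sit) / scn.t_sit_down
    y[m] = trough - H * _smoothstep(u)

    if scn.noise_sd > 0:
        noise = rng.normal(0.0, scn.noise_sd, size=(n, 3))
        x = x + noise[:, 0]
        y = y + noise[:, 1]
        z = z + noise[:, 2]

    traj = CentroidTrajectory(t=t, x=x, y=y, z=z)
    return traj, _ground_truth(scn, tl)


def _ground_truth(scn: TUGScenario, tl: _Timeline) -> GroundTruth:
    v = scn.gait_speed
    f = scn.step_frequency
    D = tl.D
    NL = scn.span_distance
    sep = scn.path_separation
    _, d_star, g = _turn_geometry(scn)

    t_start_turn = tl.wall(d_star / v)
    t_end_turn = tl.wall(D + (NL - g) / v)

    stops = tuple(tl.stop_intervals())
    events = EventSet(
        start_move=tl.t_move,
        start_walk=tl.t_walk,
        start_turn=t_start_turn,
        end_turn=t_end_turn,
        start_sit=tl.start_sit,
        end_sit=tl.end_sit,
        stops=stops,
    )

    # peaks at half-integer step phases, per span; steps pair adjacent
    # peaks of the same sub-span (never across a stop or the turn)
    N = scn.n_steps_per_span
    peak_taus = []
    for span in (0, 1):
        base = 0.0 if span == 0 else D
        peak_taus.append(base + (np.arange(N) + 0.5) / f)
    cut_taus = [c for c, _ in tl.cuts]
    times, lengths, durations = [], [], []
    for span_taus in peak_taus:
        prev = None
        for tau in span_taus:
            w = tl.wall(tau)
            times.append(w)
            if prev is not None and not any(prev < c < tau for c in cut_taus):
                durations.append(1.0 / f)
                lengths.append(scn.step_length / 10.0)
            prev = tau

    L_cm = scn.step_length / 10.0
    time_to_walk = (
        (t_start_turn - tl.t_walk)
        + (tl.start_sit - t_end_turn)
        - sum(t1 - t0 for t0, t1 in stops)
    )
    H = scn.stand_height - scn.step_oscillation_amplitude - scn.sit_height
    width_turn = math.hypot(d_star - g, sep) / 10.0
    greatest_width = math.hypot(d_star - g, sep) / 10.0

    params = TUGParameters(
        total_duration=tl.end_sit - tl.t_move,
        time_to_get_up=scn.t_get_up,
        speed_to_get_up=1.5 * H / scn.t_get_up,
        time_to_sit_down=scn.t_sit_down,
        speed_to_sit_down=-1.5 * H / scn.t_sit_down,
        time_to_walk=time_to_walk,
        n_stops=len(stops),
        width_of_turn=width_turn,
        time_of_turn=t_end_turn - t_start_turn,
        greatest_width_walk=greatest_width,
        n_steps=len(lengths),
        mean_step_length=L_cm,
        median_step_length=L_cm,
        cv_step_length=0.0,
        mean_step_duration=1.0 / f,
        median_step_duration=1.0 / f,
        cv_step_duration=0.0,
        mean_cadence=f,
        median_cadence=f,
        cv_cadence=0.0,
        gait_speed=v / 10.0,
    )
    return GroundTruth(
        events=events,
        physical_turn=(tl.turn_start, tl.turn_end),
        peak_times=np.asarray(times),
        step_lengths=np.full(len(lengths), L_cm),
        step_durations=np.full(len(durations), 1.0 / f),
        parameters=params,
        standing_height=scn.stand_height,
    )


def random_scenario(seed: int, stop_probability: float = 0.25) -> TUGScenario:
    """A realistic randomized scenario (elderly gait ranges), seeded."""
    rng = np.random.default_rng(seed)
    stand = rng.uniform(900.0, 1100.0)
    scn = TUGScenario(
        sit_height=stand * rng.uniform(0.55, 0.65),
        stand_height=stand,
        t_get_up=rng.uniform(1.0, 2.0),
        gait_speed=rng.uniform(500.0, 800.0),
        step_frequency=rng.uniform(1.4, 1.8),
        step_oscillation_amplitude=rng.uniform(12.0, 20.0),
        turn_duration=rng.uniform(1.5, 2.5),
        t_sit_down=rng.uniform(1.0, 2.0),
        noise_sd=rng.uniform(2.0, 10.0),
        seed=seed,
    )
    if rng.random() < stop_probability:
        D = scn.span_moving_duration
        side = rng.integers(0, 2)
        onset = rng.uniform(1.0, D - 1.5) + (D if side else 0.0)
        scn = dataclasses.replace(
            scn, stops=((float(onset), float(rng.uniform(0.8, 1.8))),)
        )
    return scn


# ---------------------------------------------------------------------------
# depth-frame rendering
# ---------------------------------------------------------------------------

def render_depth_sequence(
    traj: CentroidTrajectory,
    camera: CameraIntrinsics | None = None,
    body_size: tuple[float, float] | None = (500.0, None),
    background_depth_mm: float = 5000.0,
    noise_sd_mm: float = 0.0,
    seed: int = 0,
    n_background_frames: int = 5,
) -> DepthSequence:
    """Render a trajectory as 16-bit depth frames of a box-person.

    Each frame shows a flat background plane plus an upright rectangle
    ("person") of the given width whose vertical extent runs from the
    floor to twice the centroid height — so the box's 3-D centroid
    coincides with the trajectory sample.  Depth across the person is
    its centroid range, projected through the pinhole model.

    ``n_background_frames`` person-free frames are prepended (with
    timestamps extrapolated backwards) so a background model can be
    built from the head of the sequence, as a real recording would
    start before the person enters the scene.
    """
    camera = camera or CameraIntrinsics()
    width_mm = body_size[0] if body_size else 500.0
    rng = np.random.default_rng(seed)
    n_bg = int(n_background_frames)
    n = len(traj) + n_bg
    frames = np.empty((n, camera.height, camera.width), dtype=np.uint16)
    frames[:] = np.uint16(round(background_depth_mm))
    for i, (xc, yc, zc) in enumerate(zip(traj.x, traj.y, traj.z)):
        if zc <= 0:
            logger.warning("frame %d: person behind camera, skipped", i)
            continue
        c0 = int(np.ceil(camera.cx + (xc - width_mm / 2) * camera.fx / zc))
        c1 = int(np.floor(camera.cx + (xc + width_mm / 2) * camera.fx / zc))
        # rows: y in [0, 2*yc] maps downward in the image
        r0 = int(np.ceil(camera.cy - (2 * yc - camera.sensor_height_mm) * camera.fy / zc))
        r1 = int(np.floor(camera.cy + camera.sensor_height_mm * camera.fy / zc))
        if c1 < 0 or c0 >= camera.width or r1 < 0 or r0 >= camera.height:
            logger.warning("frame %d: person out of view", i)
            continue
        c0, c1 = max(c0, 0), min(c1, camera.width - 1)
        r0, r1 = max(r0, 0), min(r1, camera.height - 1)
        frames[i + n_bg, r0 : r1 + 1, c0 : c1 + 1] = np.uint16(round(zc))
    if noise_sd_mm > 0:
        noise = rng.normal(0.0, noise_sd_mm, size=frames.shape)
        frames = np.clip(frames.astype(np.int32) + np.round(noise).astype(np.int32),
                         0, 65535).astype(np.uint16)
    dt = 1.0 / traj.sampling_rate
    t_bg = traj.t[0] - dt * np.arange(n_bg, 0, -1)
    return DepthSequence(
        np.ascontiguousarray(frames),
        np.concatenate([t_bg, traj.t]),
        camera,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: Representative two-group summary statistics (mean, SD) per parameter
#: for low- vs high-fall-risk TUG cohorts, modelled on published values
#: for institutionalized elderly populations.
TWO_CLASS_STATS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "total_duration": ((12.87, 2.12), (25.78, 5.92)),
    "time_to_get_up": ((1.05, 0.35), (2.50, 1.27)),
    "speed_to_get_up": ((567.80, 127.26), (363.46, 104.14)),
    "time_to_sit_down": ((0.98, 0.59), (3.99, 2.54)),
    "speed_to_sit_down": ((-485.07, 139.44), (-221.34, 85.78)),
    "time_to_walk": ((10.84, 1.84), (19.17, 4.22)),
    "n_stops": ((0.45, 0.68), (0.94, 0.88)),
    "width_of_turn": ((387.54, 311.69), (546.13, 280.18)),
    "time_of_turn": ((1.58, 0.45), (2.99, 0.98)),
    "greatest_width_walk": ((612.14, 410.95), (813.44, 400.68)),
    "n_steps": ((6.87, 1.84), (13.51, 3.39)),
    "mean_step_length": ((48.93, 5.34), (32.81, 5.58)),
    "median_step_length": ((49.33, 5.57), (33.38, 5.84)),
    "cv_step_length": ((11.63, 7.99), (21.85, 8.71)),
    "mean_step_duration": ((0.61, 0.062), (0.73, 0.09)),
    "median_step_duration": ((0.60, 0.06), (0.72, 0.086)),
    "cv_step_duration": ((10.51, 5.53), (20.01, 6.83)),
    "mean_cadence": ((1.68, 0.16), (1.45, 0.16)),
    "median_cadence": ((1.67, 0.15), (1.41, 0.16)),
    "cv_cadence": ((10.85, 7.40), (20.89, 7.81)),
    "gait_speed": ((81.58, 11.66), (45.78, 8.59)),
}

#: Physical bounds applied to simulated parameter draws.
_PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "total_duration": (1.0, np.inf),
    "time_to_get_up": (0.1, np.inf),
    "speed_to_get_up": (10.0, np.inf),
    "time_to_sit_down": (0.1, np.inf),
    "speed_to_sit_down": (-np.inf, -10.0),
    "time_to_walk": (1.0, np.inf),
    "n_stops": (0.0, np.inf),
    "width_of_turn": (0.0, np.inf),
    "time_of_turn": (0.1, np.inf),
    "greatest_width_walk": (0.0, np.inf),
    "n_steps": (1.0, np.inf),
    "mean_step_length": (1.0, np.inf),
    "median_step_length": (1.0, np.inf),
    "cv_step_length": (0.0, np.inf),
    "mean_step_duration": (0.1, np.inf),
    "median_step_duration": (0.1, np.inf),
    "cv_step_duration": (0.0, np.inf),
    "mean_cadence": (0.1, np.inf),
    "median_cadence": (0.1, np.inf),
    "cv_cadence": (0.0, np.inf),
    "gait_speed": (1.0, np.inf),
}

_INTEGER_PARAMS = ("n_steps", "n_stops")


@dataclass(frozen=True)
class CohortSpec:
    """Distributional template for a multi-subject synthetic cohort.

    ``stats[param][c]`` is the (mean, SD) of a parameter in class ``c``.
    Parameters share a uniform between-parameter correlation
    ``correlation`` at the subject level; each subject contributes
    ``trials_per_subject`` trials whose values jitter around the
    subject's own level with SD ``within_sd_frac`` times the class SD.
    """

    counts: tuple[int, ...]
    stats: dict[str, tuple[tuple[float, float], ...]]
    class_labels: tuple[int, ...] | None = None
    correlation: float = 0.3
    trials_per_subject: int = 3
    within_sd_frac: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if sum(self.counts) == 0:
            raise ValueError("empty cohort")
        for name, per_class in self.stats.items():
            if len(per_class) != len(self.counts):
                raise ValueError(f"{name}: one (mean, SD) pair per class required")
            if any(sd < 0 for _, sd in per_class):
                raise ValueError(f"{name}: negative SD")


def two_class_cohort_spec(
    n_low: int = 11, n_high: int = 26, correlation: float = 0.3
) -> CohortSpec:
    """Default low-risk vs at-risk cohort template."""
    return CohortSpec(counts=(n_low, n_high), stats=dict(TWO_CLASS_STATS),
                      correlation=correlation)


def three_class_cohort_spec(
    counts: tuple[int, int, int] = (13, 5, 16), correlation: float = 0.3
) -> CohortSpec:
    """Three-class (no risk / moderate / rehabilitation) template.

    Class 0 matches the low-risk column, class 2 the at-risk column,
    and the small intermediate class sits between them; gait variables
    (step count, cadence, duration, gait speed) carry most separation.
    """
    stats: dict[str, tuple[tuple[float, float], ...]] = {}
    for name, (low, high) in TWO_CLASS_STATS.items():
        mid = ((low[0] + high[0]) / 2.0, (low[1] + high[1]) / 2.0)
        stats[name] = (low, mid, high)
    return CohortSpec(counts=counts, stats=stats, correlation=correlation)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table: one row per (subject, trial).

    Subject-level parameter vectors are multivariate normal with the
    class means/SDs and a uniform correlation; trials add small
    within-subject jitter; draws are clipped to physical bounds and the
    count parameters rounded.  ``best_trial`` flags each subject's
    minimum total duration; ``grid_class`` is the class label.
    """
    if seed is None:
        seed = spec.seed if spec.seed is not None else 0
    rng = np.random.default_rng(seed)
    names = [n for n in PARAMETER_NAMES if n in spec.stats]
    extra = [n for n in spec.stats if n not in PARAMETER_NAMES]
    names += extra
    p = len(names)
    R = np.full((p, p), spec.correlation)
    np.fill_diagonal(R, 1.0)
    chol = np.linalg.cholesky(R)

    labels = spec.class_labels or tuple(range(len(spec.counts)))
    rows = []
    subject = 0
    for ci, count in enumerate(spec.counts):
        mu = np.array([spec.stats[n][ci][0] for n in names])
        sd = np.array([spec.stats[n][ci][1] for n in names])
        for _ in range(count):
            base = mu + sd * (chol @ rng.standard_normal(p))
            for trial in range(1, spec.trials_per_subject + 1):
                vals = base + sd * spec.within_sd_frac * rng.standard_normal(p)
                row = {"subject": subject, "trial": trial, "grid_class": labels[ci]}
                for name, val in zip(names, vals):
                    lo, hi = _PARAM_BOUNDS.get(name, (-np.inf, np.inf))
                    val = float(np.clip(val, lo, hi))
                    if name in _INTEGER_PARAMS:
                        val = float(round(val))
                    row[name] = val
                rows.append(row)
            subject += 1
    df = pd.DataFrame(rows)
    best = df.loc[df.groupby("subject")["total_duration"].idxmin()].index
    df["best_trial"] = False
    df.loc[best, "best_trial"] = True
    return df
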