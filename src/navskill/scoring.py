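"""Trajectory error measures for the simple spatial tasks and navigation.

Every task score is built from up to four components, each mapped onto
[0, 1] (0 = optimal, 1 = maximally wrong):

* final rotation error  — minimal circular difference between the final
  viewing direction and the bearing to the goal, divided by 180;
* cumulative rotation error — per resampled time step, 0 if the observer
  rotated towards the goal, 1 if away, 0.5 if static; averaged over steps;
* final distance error  — |d_e - delta_c| / (d_s - delta_c), clamped at 1,
  where delta_c is the catchment offset (the interaction circle is centred
  ~4 m ahead of the observer, so stopping delta_c short of the goal is a
  perfect response);
* cumulative distance error — per step, how far the achieved approach fell
  short of the best approach reachable with that step's displacement:
  (d_next - d_opt) / (2 * step), d_opt = max(0, d - step); 0.5 if static.

Rotation-only tasks (ROT, RWM, RFM — translations disabled) combine the two
rotation components /2; all other tasks combine all four /4.  Navigation
performance is the distance-error ratio r_d = walked / optimal route
length, with 1.0 = perfect.

The per-step classifications use small static thresholds so that sensor
jitter is not scored as movement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from navskill.trajio import TrialLog, path_length

__all__ = [
    "ScoringConfig",
    "ErrorComponents",
    "TaskScore",
    "NavScore",
    "ROTATION_ONLY_TASKS",
    "circular_difference",
    "final_rotation_error",
    "cumulative_rotation_error",
    "final_distance_error",
    "cumulative_distance_error",
    "combined_task_error",
    "score_trial",
    "aggregate_and_standardize",
    "task_completion_time",
    "shortest_route_distance",
    "navigation_distance_ratio",
    "StreamingRotationError",
    "StreamingDistanceError",
]

ROTATION_ONLY_TASKS = frozenset({"ROT", "RWM", "RFM"})


@dataclass(frozen=True)
class ScoringConfig:
    """Scoring constants.

    catchment_offset: meters between observer and catchment-circle centre.
    dt: resampling step, seconds.
    static_rot_threshold: degrees/step below which a rotation counts as
        static.
    static_dist_threshold: meters/step below which a translation counts as
        static.
    weighted_rotation: if True, weight each step of the cumulative rotation
        error by its rotation magnitude (share of total turning) instead of
        equal step weights.
    """

    catchment_offset: float = 4.0
    dt: float = 0.1
    static_rot_threshold: float = 0.5
    static_dist_threshold: float = 0.005
    weighted_rotation: bool = False

    def __post_init__(self) -> None:
        if self.catchment_offset <= 0:
            raise ValueError("catchment_offset must be > 0")
        if self.static_rot_threshold < 0 or self.static_dist_threshold < 0:
            raise ValueError("static thresholds must be >= 0")


@dataclass(frozen=True)
class ErrorComponents:
    """The four [0, 1] error components of one trial."""

    final_rotation: float
    cumulative_rotation: float
    final_distance: float
    cumulative_distance: float

    def __post_init__(self) -> None:
        for name in ("final_rotation", "cumulative_rotation", "final_distance", "cumulative_distance"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class TaskScore:
    """Combined error and completion time of one simple-task trial."""

    task: str
    combined: float
    time: float
    components: ErrorComponents


@dataclass
class NavScore:
    """Per-participant navigation summary."""

    participant: str
    mean_ratio: float
    trial_ratios: list = field(default_factory=list)
    trigger_counts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# angles


def circular_difference(a, b):
    """Minimal absolute angular difference in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


def _bearing(from_xy: np.ndarray, to_xy: np.ndarray) -> np.ndarray:
    """Bearing in degrees from each row of from_xy to the matching row of to_xy."""
    d = np.atleast_2d(to_xy) - np.atleast_2d(from_xy)
    return np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 360.0


def final_rotation_error(yaw: float, bearing_to_goal: float) -> float:
    """Final rotation error: circular difference / 180, in [0, 1]."""
    return float(circular_difference(yaw, bearing_to_goal)) / 180.0


def final_distance_error(d_s: float, d_e: float, catchment_offset: float = 4.0) -> float:
    """Final distance error relative to the start distance.

    0 when the goal was reached up to the catchment precision, 1 when the
    end distance is at least the start distance.  A start already inside
    the catchment (d_s <= offset) is scored 0/1 by goal attainment, since
    the ratio's denominator degenerates.
    """
    if d_s < 0 or d_e < 0:
        raise ValueError("distances must be non-negative")
    dc = catchment_offset
    if d_s <= dc:
        return 0.0 if d_e <= dc else 1.0
    return min(1.0, abs(d_e - dc) / (d_s - dc))


def _goal_track(traj: TrialLog, goal) -> np.ndarray:
    """(n, 2) goal position per pose sample; static point or dynamic series."""
    n = len(traj.poses)
    goal = np.asarray(goal, dtype=float)
    if goal.ndim == 1:
        return np.broadcast_to(goal, (n, 2)).copy()
    if goal.shape[1] == 3:  # (t, x, y) series on the same grid
        goal = goal[:, 1:]
    if len(goal) != n:
        if np.ptp(goal, axis=0).max() < 1e-12:  # static sphere, sparse series
            return np.broadcast_to(goal[0], (n, 2)).copy()
        raise ValueError(
            f"goal series length {len(goal)} != number of poses {n}; "
            "resample the trial onto a uniform grid first"
        )
    return goal


def cumulative_rotation_error(traj: TrialLog, goal, config: ScoringConfig = ScoringConfig()) -> float:
    """Mean per-step rotation penalty: toward-goal 0, away 1, static 0.5.

    Expects a uniformly resampled trajectory.  For dynamic targets the
    bearing is re-evaluated every step.  With ``weighted_rotation`` steps
    are weighted by their share of the total rotation magnitude.
    """
    goal_xy = _goal_track(traj, goal)
    if len(traj.poses) < 2:
        raise ValueError("cumulative rotation error needs at least one step")
    bearings = _bearing(traj.xy, goal_xy)
    err = circular_difference(traj.yaw, bearings)
    dyaw = circular_difference(traj.yaw[1:], traj.yaw[:-1])
    static = dyaw < config.static_rot_threshold
    toward = err[1:] < err[:-1]
    away = err[1:] > err[:-1]
    step_err = np.where(static | (~toward & ~away), 0.5, np.where(away, 1.0, 0.0))
    if config.weighted_rotation:
        total = float(np.sum(np.where(static, 0.0, dyaw)))
        if total <= 0:
            return 0.5
        w = np.where(static, 0.0, dyaw) / total
        return float(np.sum(w * step_err))
    return float(np.mean(step_err))


def cumulative_distance_error(traj: TrialLog, goal, config: ScoringConfig = ScoringConfig()) -> float:
    """Mean per-step distance penalty in [0, 1].

    Per step, the best reachable distance is d_opt = max(0, d - step);
    moving straight toward the goal scores 0, straight away 1, and a
    static step 0.5.
    """
    goal_xy = _goal_track(traj, goal)
    if len(traj.poses) < 2:
        raise ValueError("cumulative distance error needs at least one step")
    d = np.hypot(*(goal_xy - traj.xy).T)
    step = np.hypot(*np.diff(traj.xy, axis=0).T)
    static = step < config.static_dist_threshold
    d_opt = np.maximum(0.0, d[:-1] - step)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (d[1:] - d_opt) / (2.0 * step)
    step_err = np.where(static, 0.5, np.clip(raw, 0.0, 1.0))
    return float(np.mean(step_err))


class StreamingRotationError:
    """One-pass accumulator matching :func:`cumulative_rotation_error`.

    Feed (yaw, goal-bearing error) one sample at a time via
    :meth:`update`; ``value`` is the running mean step penalty.
    """

    def __init__(self, config: ScoringConfig = ScoringConfig()):
        self._cfg = config
        self._prev: tuple[float, float] | None = None
        self._sum = 0.0
        self._wsum = 0.0
        self._n = 0

    def update(self, yaw: float, bearing: float) -> None:
        err = float(circular_difference(yaw, bearing))
        if self._prev is not None:
            prev_yaw, prev_err = self._prev
            dyaw = float(circular_difference(yaw, prev_yaw))
            if dyaw < self._cfg.static_rot_threshold or err == prev_err:
                pen, w = 0.5, 0.0
            elif err > prev_err:
                pen, w = 1.0, dyaw
            else:
                pen, w = 0.0, dyaw
            if self._cfg.weighted_rotation:
                self._sum += w * pen
                self._wsum += w
            else:
                self._sum += pen
            self._n += 1
        self._prev = (yaw, err)

    @property
    def value(self) -> float:
        if self._n == 0:
            raise ValueError("no steps accumulated")
        if self._cfg.weighted_rotation:
            return self._sum / self._wsum if self._wsum > 0 else 0.5
        return self._sum / self._n


class StreamingDistanceError:
    """One-pass accumulator matching :func:`cumulative_distance_error`."""

    def __init__(self, config: ScoringConfig = ScoringConfig()):
        self._cfg = config
        self._prev: tuple[float, float, float] | None = None  # x, y, d
        self._sum = 0.0
        self._n = 0

    def update(self, x: float, y: float, goal_x: float, goal_y: float) -> None:
        d = math.hypot(goal_x - x, goal_y - y)
        if self._prev is not None:
            px, py, pd = self._prev
            step = math.hypot(x - px, y - py)
            if step < self._cfg.static_dist_threshold:
                pen = 0.5
            else:
                d_opt = max(0.0, pd - step)
                pen = min(1.0, max(0.0, (d - d_opt) / (2.0 * step)))
            self._sum += pen
            self._n += 1
        self._prev = (x, y, d)

    @property
    def value(self) -> float:
        if self._n == 0:
            raise ValueError("no steps accumulated")
        return self._sum / self._n


# ---------------------------------------------------------------------------
# combination and aggregation


def combined_task_error(components: ErrorComponents, task: str) -> float:
    """Combine components: /2 for rotation-only tasks, /4 otherwise."""
    if task in ROTATION_ONLY_TASKS:
        return (components.final_rotation + components.cumulative_rotation) / 2.0
    return (
        components.final_rotation
        + components.cumulative_rotation
        + components.final_distance
        + components.cumulative_distance
    ) / 4.0


def task_completion_time(trial: TrialLog) -> float:
    """Trigger time minus trial start time, seconds."""
    if len(trial.triggers) == 0:
        raise ValueError(f"trial {trial.task} block {trial.block} has no completion trigger")
    dt = float(trial.triggers[-1] - trial.poses[0, 0])
    if dt < 0:
        raise ValueError(f"completion trigger precedes trial start ({dt:.3f} s)")
    return dt


def score_trial(trial: TrialLog, config: ScoringConfig = ScoringConfig()) -> TaskScore:
    """Score one simple-task trial against its (possibly moving) target."""
    goal = trial.target_series()
    if goal is None:
        raise ValueError(f"trial {trial.task} block {trial.block} has no target sphere")
    goal_xy = _goal_track(trial, goal)
    d = np.hypot(*(goal_xy - trial.xy).T)
    comps = ErrorComponents(
        final_rotation=final_rotation_error(
            trial.yaw[-1], float(_bearing(trial.xy[-1:], goal_xy[-1:])[0])
        ),
        cumulative_rotation=cumulative_rotation_error(trial, goal_xy, config),
        final_distance=final_distance_error(float(d[0]), float(d[-1]), config.catchment_offset),
        cumulative_distance=cumulative_distance_error(trial, goal_xy, config),
    )
    return TaskScore(
        task=trial.task,
        combined=combined_task_error(comps, trial.task),
        time=task_completion_time(trial),
        components=comps,
    )


def aggregate_and_standardize(errors: pd.DataFrame) -> pd.DataFrame:
    """Participant x task z-score matrix from long-format trial errors.

    ``errors`` needs columns participant, task, error (one row per
    repetition).  Per participant x task the repetitions are averaged;
    each task column is then standardized across participants with the
    sample (n-1) standard deviation.
    """
    required = {"participant", "task", "error"}
    if not required.issubset(errors.columns):
        raise ValueError(f"errors frame needs columns {sorted(required)}")
    means = errors.groupby(["participant", "task"])["error"].mean().unstack("task")
    if means.isna().any().any():
        missing = means.columns[means.isna().any()].tolist()
        raise ValueError(f"missing repetitions for task column(s) {missing}")
    if len(means) < 2:
        raise ValueError("standardization needs at least 2 participants")
    sd = means.std(ddof=1)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise ValueError(f"zero variance in task column(s) {zero}; cannot standardize")
    return (means - means.mean()) / sd


# ---------------------------------------------------------------------------
# navigation


def shortest_route_distance(network, source, target) -> float:
    """Minimum route length between two nodes of a road network (Dijkstra)."""
    graph = network if isinstance(network, nx.Graph) else network.graph
    try:
        return float(nx.shortest_path_length(graph, source, target, weight="length"))
    except nx.NetworkXNoPath as exc:
        raise ValueError(f"nodes {source!r} and {target!r} are disconnected") from exc
    except nx.NodeNotFound as exc:
        raise ValueError(str(exc)) from exc


def navigation_distance_ratio(walked: TrialLog, optimal_distance: float) -> float:
    """Distance-error ratio r_d = walked path length / optimal route length."""
    if optimal_distance <= 0:
        raise ValueError("optimal route distance must be positive")
    return path_length(walked.xy) / optimal_distance
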