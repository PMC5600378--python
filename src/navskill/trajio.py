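"""Trial-log schema, CSV round-trip, and uniform-time resampling.

A session log is a flat delimited file with one row per observation:

``participant,phase,task,block,t,x,y,yaw,entity,event``

* ``entity`` is ``observer`` for pose samples, ``sphere_<id>`` for a
  plain sphere sample and ``target_<id>`` for a sample of a sphere flagged
  as the (blue) target;
* ``event`` is empty for ordinary samples, ``start``/``end`` on the first
  and last row of a trial, and ``trigger`` for a joystick trigger press;
* times are seconds from trial start, positions meters, yaw degrees in
  [0, 360).

Trials are identified by the (participant, phase, task, block) key and
must carry explicit start/end indicator rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "PoseSample",
    "TrialLog",
    "TrialLogError",
    "read_trial_logs",
    "write_trial_logs",
    "resample_trajectory",
    "path_length",
]

COLUMNS = ["participant", "phase", "task", "block", "t", "x", "y", "yaw", "entity", "event"]
PHASES = ("training", "navigation", "simple")


class TrialLogError(ValueError):
    """Malformed trial log (schema, ordering or indicator problems)."""


@dataclass(frozen=True)
class PoseSample:
    """One time-stamped observer state."""

    t: float
    x: float
    y: float
    yaw: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise TrialLogError(f"pose time must be non-negative, got {self.t}")
        object.__setattr__(self, "yaw", float(self.yaw) % 360.0)


@dataclass
class TrialLog:
    """All samples, sphere states and trigger events of one trial.

    ``poses`` is an (n, 4) float array with columns (t, x, y, yaw);
    ``sphere_series`` maps sphere id to an (m, 3) array (t, x, y);
    ``target_ids`` flags which spheres are targets; ``triggers`` holds
    trigger-press times (trial-relative seconds).
    """

    participant: str
    phase: str
    task: str
    block: int
    poses: np.ndarray
    sphere_series: dict[int, np.ndarray] = field(default_factory=dict)
    target_ids: frozenset = frozenset()
    triggers: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.poses = np.asarray(self.poses, dtype=float)
        self.triggers = np.asarray(self.triggers, dtype=float)
        if self.phase not in PHASES:
            raise TrialLogError(f"unknown phase {self.phase!r} (expected one of {PHASES})")
        if self.poses.ndim != 2 or self.poses.shape[1] != 4:
            raise TrialLogError("poses must be an (n, 4) array of (t, x, y, yaw)")
        if len(self.poses) < 2:
            raise TrialLogError(
                f"trial {self._key()} has {len(self.poses)} pose(s); at least 2 required"
            )
        t = self.poses[:, 0]
        if np.any(np.diff(t) < 0):
            raise TrialLogError(f"non-monotone time within trial {self._key()}")
        self.poses[:, 3] %= 360.0
        if self.phase == "simple" and len(self.triggers) != 1:
            raise TrialLogError(
                f"simple-task trial {self._key()} must have exactly one completion "
                f"trigger, found {len(self.triggers)}"
            )

    def _key(self) -> tuple:
        return (self.participant, self.phase, self.task, self.block)

    @property
    def times(self) -> np.ndarray:
        return self.poses[:, 0]

    @property
    def xy(self) -> np.ndarray:
        return self.poses[:, 1:3]

    @property
    def yaw(self) -> np.ndarray:
        return self.poses[:, 3]

    @property
    def duration(self) -> float:
        return float(self.poses[-1, 0] - self.poses[0, 0])

    def target_series(self) -> np.ndarray | None:
        """(m, 3) series of the unique target sphere, or None."""
        if not self.target_ids:
            return None
        tid = min(self.target_ids)
        return self.sphere_series[tid]


def path_length(xy: np.ndarray) -> float:
    """Polyline length of an (n, 2) position array, meters."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        raise TrialLogError("path length needs at least 2 positions")
    return float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))


# ---------------------------------------------------------------------------
# CSV round-trip


def write_trial_logs(logs: Iterable[TrialLog], path) -> None:
    """Write trials to the flat CSV schema (stable column order, 6 d.p.)."""
    rows: list[tuple] = []
    for log in logs:
        n = len(log.poses)
        for i, (t, x, y, yaw) in enumerate(log.poses):
            event = "start" if i == 0 else ("end" if i == n - 1 else "")
            rows.append(
                (log.participant, log.phase, log.task, log.block, t, x, y, yaw, "observer", event)
            )
        for t in log.triggers:
            rows.append(
                (log.participant, log.phase, log.task, log.block, t, np.nan, np.nan, np.nan, "observer", "trigger")
            )
        for sid, series in sorted(log.sphere_series.items()):
            name = f"target_{sid}" if sid in log.target_ids else f"sphere_{sid}"
            for t, x, y in series:
                rows.append(
                    (log.participant, log.phase, log.task, log.block, t, x, y, np.nan, name, "")
                )
    frame = pd.DataFrame(rows, columns=COLUMNS)
    frame.to_csv(path, index=False, float_format="%.6f")


def read_trial_logs(path) -> list[TrialLog]:
    """Parse the flat CSV schema back into :class:`TrialLog` objects.

    Rows are grouped by (participant, phase, task, block); each group must
    carry ``start``/``end`` indicator rows and monotone observer time.
    Malformed rows are reported with their file line number.
    """
    frame = pd.read_csv(path, dtype={"participant": str, "task": str, "event": str, "entity": str})
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise TrialLogError(f"missing columns in {path}: {missing}")
    frame["event"] = frame["event"].fillna("")
    bad = frame.index[~frame["phase"].isin(PHASES)]
    if len(bad):
        raise TrialLogError(f"unknown phase at file line {bad[0] + 2} in {path}")
    logs = []
    for key, grp in frame.groupby(["participant", "phase", "task", "block"], sort=False):
        logs.append(_parse_trial(key, grp, path))
    logs.sort(key=lambda lg: (lg.participant, lg.phase, lg.block, lg.task))
    return logs


def _parse_trial(key: tuple, grp: pd.DataFrame, path) -> TrialLog:
    participant, phase, task, block = key
    obs = grp[grp["entity"] == "observer"]
    poses = obs[obs["event"] != "trigger"]
    t = poses["t"].to_numpy(float)
    if np.any(np.diff(t) < 0):
        i = int(np.flatnonzero(np.diff(t) < 0)[0])
        raise TrialLogError(
            f"non-monotone time in trial {key} near file line {poses.index[i + 1] + 2} of {path}"
        )
    events = poses["event"].tolist()
    if not events or events[0] != "start" or events[-1] != "end":
        raise TrialLogError(f"trial {key} lacks start/end indicators in {path}")
    spheres: dict[int, np.ndarray] = {}
    targets = set()
    for name, sub in grp[grp["entity"] != "observer"].groupby("entity"):
        kind, _, sid = str(name).partition("_")
        if kind not in ("sphere", "target") or not sid.isdigit():
            raise TrialLogError(
                f"unknown entity {name!r} at file line {sub.index[0] + 2} of {path}"
            )
        sid = int(sid)
        spheres[sid] = sub[["t", "x", "y"]].to_numpy(float)
        if kind == "target":
            targets.add(sid)
    return TrialLog(
        participant=str(participant),
        phase=str(phase),
        task=str(task),
        block=int(block),
        poses=poses[["t", "x", "y", "yaw"]].to_numpy(float),
        sphere_series=spheres,
        target_ids=frozenset(targets),
        triggers=obs.loc[obs["event"] == "trigger", "t"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# Resampling


def _interp_series(tq: np.ndarray, t: np.ndarray, series: np.ndarray) -> np.ndarray:
    cols = [np.interp(tq, t, series[:, j]) for j in range(series.shape[1])]
    return np.column_stack(cols)


def resample_trajectory(log: TrialLog, dt: float) -> TrialLog:
    """Resample a trial to a uniform time base t = 0, dt, 2dt, ... <= t_end.

    Positions are linearly interpolated between the two bracketing samples
    with weights proportional to temporal proximity; yaw is interpolated
    along the shortest circular arc (so 350 deg -> 10 deg passes through 0,
    never through 180). Sphere series are resampled onto the same grid.
    Trigger times are preserved (they are events, not samples).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    t0 = log.poses[0, 0]
    t = log.times - t0
    t_end = t[-1]
    if dt > t_end:
        raise ValueError(
            f"dt={dt} exceeds trial duration {t_end:.6g} for trial "
            f"{(log.participant, log.phase, log.task, log.block)}"
        )
    n_steps = int(math.floor(t_end / dt + 1e-9))
    tq = np.arange(n_steps + 1) * dt
    x = np.interp(tq, t, log.poses[:, 1])
    y = np.interp(tq, t, log.poses[:, 2])
    yaw_unwrapped = np.unwrap(log.yaw, period=360.0)
    yaw = np.interp(tq, t, yaw_unwrapped) % 360.0
    spheres = {
        sid: np.column_stack(
            [tq, _interp_series(tq, series[:, 0] - t0, series[:, 1:])]
        )
        for sid, series in log.sphere_series.items()
    }
    return TrialLog(
        participant=log.participant,
        phase=log.phase,
        task=log.task,
        block=log.block,
        poses=np.column_stack([tq, x, y, yaw]),
        sphere_series=spheres,
        target_ids=log.target_ids,
        triggers=log.triggers - t0,
    )
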