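"""Synthetic-agent simulator for the sphere-field tasks and navigation.

The simulator emulates the statistical structure of a VR navigation study:
agents with latent skills perform eight simple spatial tasks (five blocks)
in a 40 m x 40 m field of floating spheres, and a multi-block navigation
phase on a small road network with six goal locations.

Agents are controlled by intentionally simple proportional heading
controllers with Gaussian noise; only the induced structure of the error
scores matters, not behavioural realism.  Three skills plus a navigation
ability are derived from standard-normal latent factors via a loading
matrix, so correlations between task performances and navigation
performance can be planted (or removed, for null worlds) by construction:

* ``motor_skill``     — precision of heading/speed control with the input
  device.  It perturbs every task, but continuous pursuit (the chase
  tasks) stresses it far harder than the discrete aim-and-stop actions of
  the static tasks, so its noise scale is much larger for dynamic tasks.
* ``memory_fidelity`` — accuracy of remembered bearings/positions
  (rotate/move-from-memory tasks).
* ``map_skill``       — accuracy of translating top-down map information
  into egocentric action (with-map tasks).
* ``nav_skill``       — wayfinding ability; sets the wrong-turn
  probability and the guidance-arrow usage in the navigation phase.

The default loading matrix shares one latent factor between motor skill
and navigation ability with correlation 0.6; :data:`NULL_LOADINGS` removes
the link for type-I-error checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import ndtr

from navskill.trajio import TrialLog

__all__ = [
    "TASK_CODES",
    "TASKS",
    "TaskSpec",
    "SphereField",
    "AgentParams",
    "RoadNetwork",
    "SimConfig",
    "DEFAULT_LOADINGS",
    "NULL_LOADINGS",
    "make_sphere_field",
    "simulate_sphere_motion",
    "simulate_simple_task",
    "simulate_navigation",
    "simulate_session",
    "make_population",
    "make_grid_network",
    "make_factor_scores",
    "check_rotation_only",
]


# ---------------------------------------------------------------------------
# task classification


@dataclass(frozen=True)
class TaskSpec:
    """One simple task's position on the four binary design dimensions."""

    code: str
    dynamic: bool
    remembered: bool
    allocentric: bool
    judgement: str  # "distance", "direction" or "both"

    def __post_init__(self) -> None:
        if self.judgement not in ("distance", "direction", "both"):
            raise ValueError(f"bad judgement {self.judgement!r}")
        if self.dynamic and self.remembered:
            raise ValueError("dynamic x remembered tasks are excluded by design")
        if self.remembered and self.allocentric:
            raise ValueError("remembered x allocentric tasks are excluded by design")


TASKS: dict[str, TaskSpec] = {
    "ROT": TaskSpec("ROT", dynamic=False, remembered=False, allocentric=False, judgement="direction"),
    "MOV": TaskSpec("MOV", dynamic=False, remembered=False, allocentric=False, judgement="distance"),
    "RWM": TaskSpec("RWM", dynamic=False, remembered=False, allocentric=True, judgement="direction"),
    "MWM": TaskSpec("MWM", dynamic=False, remembered=False, allocentric=True, judgement="distance"),
    "RFM": TaskSpec("RFM", dynamic=False, remembered=True, allocentric=False, judgement="direction"),
    "MFM": TaskSpec("MFM", dynamic=False, remembered=True, allocentric=False, judgement="distance"),
    "CHA": TaskSpec("CHA", dynamic=True, remembered=False, allocentric=False, judgement="both"),
    "CWM": TaskSpec("CWM", dynamic=True, remembered=False, allocentric=True, judgement="both"),
}
TASK_CODES = tuple(TASKS)
ROTATION_ONLY = frozenset({"ROT", "RWM", "RFM"})


# ---------------------------------------------------------------------------
# sphere field


@dataclass(frozen=True)
class SphereField:
    """A square field of floating spheres.

    positions: (n, 2) sphere centres in meters; ids are row indices.
    """

    side: float
    positions: np.ndarray
    target_ids: frozenset
    radius: float = 0.25
    min_separation: float = 2.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if np.any(pos < 0) or np.any(pos > self.side):
            raise ValueError("sphere positions outside field bounds")
        if len(pos) > 1:
            d = np.hypot(*(pos[:, None, :] - pos[None, :, :]).T)
            np.fill_diagonal(d, np.inf)
            if d.min() < self.min_separation - 1e-9:
                raise ValueError(
                    f"sphere separation {d.min():.3f} m below minimum {self.min_separation} m"
                )
        if not set(self.target_ids) <= set(range(len(pos))):
            raise ValueError("target_ids must be sphere ids")


def make_sphere_field(
    n_spheres: int,
    side: float = 40.0,
    min_sep: float = 2.0,
    rng: np.random.Generator | int | None = None,
    n_targets: int = 1,
    max_attempts: int = 10_000,
) -> SphereField:
    """Place spheres uniformly at random with a minimum pairwise separation.

    Rejection sampling; raises if the requested density cannot be met
    within ``max_attempts`` draws.
    """
    rng = np.random.default_rng(rng)
    pos = np.empty((n_spheres, 2))
    n_placed = 0
    attempts = 0
    sep2 = min_sep**2
    while n_placed < n_spheres:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n_spheres} spheres with min separation {min_sep} m "
                f"in a {side} m field after {max_attempts} attempts; reduce the density"
            )
        k = max(16, n_spheres - n_placed)
        pts = rng.uniform(0.0, side, size=(k, 2))
        attempts += k
        for p in pts:
            if n_placed >= n_spheres:
                break
            d2 = (pos[:n_placed, 0] - p[0]) ** 2 + (pos[:n_placed, 1] - p[1]) ** 2
            if n_placed == 0 or d2.min() >= sep2:
                pos[n_placed] = p
                n_placed += 1
    positions = pos
    targets = frozenset(rng.choice(n_spheres, size=min(n_targets, n_spheres), replace=False).tolist())
    return SphereField(side=side, positions=positions, target_ids=targets, min_separation=min_sep)


def simulate_sphere_motion(
    field: SphereField,
    duration: float,
    dt: float,
    speed: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Random-waypoint motion for all spheres.

    Each sphere heads towards a uniformly drawn waypoint at constant
    ``speed``, drawing a new waypoint on arrival.  Returns an
    (n_steps + 1, n_spheres, 2) position array sampled at ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if speed < 0:
        raise ValueError("speed must be non-negative")
    rng = np.random.default_rng(rng)
    n = len(field.positions)
    n_steps = int(round(duration / dt))
    pos = field.positions.copy()
    waypoints = rng.uniform(0.0, field.side, size=(n, 2))
    out = np.empty((n_steps + 1, n, 2))
    out[0] = pos
    step_max = speed * dt
    for i in range(1, n_steps + 1):
        if step_max > 0:
            delta = waypoints - pos
            dist = np.hypot(delta[:, 0], delta[:, 1])
            arrive = dist <= step_max
            scale = np.where(arrive, 1.0, step_max / np.maximum(dist, 1e-12))
            pos = pos + delta * scale[:, None]
            n_arr = int(arrive.sum())
            if n_arr:
                waypoints[arrive] = rng.uniform(0.0, field.side, size=(n_arr, 2))
            np.clip(pos, 0.0, field.side, out=pos)
        out[i] = pos
    return out


# ---------------------------------------------------------------------------
# agents


DEFAULT_LOADINGS = np.array(
    [
        [0.9, 0.0, 0.0, 0.0],  # motor_skill      <- HID/perceptuomotor factor
        [0.0, 0.9, 0.0, 0.0],  # memory_fidelity  <- memory factor
        [0.0, 0.0, 0.9, 0.0],  # map_skill        <- map-reading factor
        [2.0 / 3.0, 0.0, 0.0, 0.0],  # nav_skill  <- shares the HID factor: corr 0.6
        [0.0, 0.0, 0.0, 0.9],  # aim_precision    <- static aim/stop carefulness
    ]
)
"""Default latent loading matrix (rows: motor, memory, map, nav, aim).

corr(motor raw, nav raw) = 0.9 * (2/3) = 0.6 — the planted link between
dynamic-task skill and navigation ability.  Aim precision (the dominant
individual difference on the static aim-and-stop tasks) is deliberately
independent of navigation, so static composites are null predictors by
construction."""

NULL_LOADINGS = DEFAULT_LOADINGS.copy()
NULL_LOADINGS[3] = 0.0
"""Loading matrix for null worlds: navigation shares no factor with any skill."""


@dataclass(frozen=True)
class AgentParams:
    """Latent-skill parameters of one synthetic agent (all skills in (0, 1])."""

    motor_skill: float
    memory_fidelity: float
    map_skill: float
    nav_skill: float = 0.5
    aim_precision: float = 0.5
    speed: float = 2.0
    turn_rate: float = 120.0
    latent_factors: tuple = ()

    def __post_init__(self) -> None:
        for name in ("motor_skill", "memory_fidelity", "map_skill", "nav_skill", "aim_precision"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name}={v} outside (0, 1]")

    @classmethod
    def from_latent(
        cls,
        latent: np.ndarray,
        loadings: np.ndarray = DEFAULT_LOADINGS,
        rng: np.random.Generator | int | None = None,
        **kwargs,
    ) -> "AgentParams":
        """Derive skills from standard-normal latent factors.

        Each row w of ``loadings`` (norm <= 1) defines a raw ability
        w . latent + sqrt(1 - |w|^2) * e with e ~ N(0, 1); the raw score is
        squashed to (0, 1] through the normal CDF.
        """
        rng = np.random.default_rng(rng)
        latent = np.asarray(latent, dtype=float)
        loadings = np.asarray(loadings, dtype=float)
        norms2 = np.sum(loadings**2, axis=1)
        if np.any(norms2 > 1.0 + 1e-9):
            raise ValueError("loading matrix rows must have norm <= 1")
        raw = loadings @ latent + np.sqrt(np.maximum(0.0, 1.0 - norms2)) * rng.standard_normal(
            len(loadings)
        )
        sk = np.clip(ndtr(raw), 0.02, 1.0)
        return cls(
            motor_skill=float(sk[0]),
            memory_fidelity=float(sk[1]),
            map_skill=float(sk[2]),
            nav_skill=float(sk[3]),
            aim_precision=float(sk[4]) if len(sk) > 4 else 0.5,
            latent_factors=tuple(latent),
            **kwargs,
        )


def make_population(
    n_agents: int,
    loadings: np.ndarray = DEFAULT_LOADINGS,
    rng: np.random.Generator | int | None = None,
    n_factors: int | None = None,
) -> list[AgentParams]:
    """Draw a population of agents from the latent-factor model."""
    rng = np.random.default_rng(rng)
    loadings = np.asarray(loadings, dtype=float)
    m = n_factors if n_factors is not None else loadings.shape[1]
    return [
        AgentParams.from_latent(rng.standard_normal(m), loadings=loadings, rng=rng)
        for _ in range(n_agents)
    ]


# ---------------------------------------------------------------------------
# simulation configuration


@dataclass(frozen=True)
class SimConfig:
    """Study-design constants and controller noise scales.

    Field and timing constants mirror the emulated design (40 m field,
    20 spheres with 2 m separation, 0.25 m radius, five blocks of eight
    tasks, 3 learning + 1 testing navigation blocks, dt = 0.1 s).  Sphere
    speed and the interception radius for the chase tasks are not fixed by
    the design and are configurable (defaults: 1 m/s and the 4 m catchment
    radius; unvalidated choices).  Noise scales are the controller's
    standard deviations at skill = 0; every scale multiplies (1 - skill).
    """

    field_side: float = 40.0
    n_spheres: int = 20
    sphere_min_sep: float = 2.0
    dt: float = 0.1
    n_blocks: int = 5
    catchment_offset: float = 4.0
    # chase-task constants (unvalidated, configurable)
    sphere_speed: float = 1.0
    intercept_radius: float = 4.0
    log_distractor_motion: bool = False  # distractor spheres are scenery
    # trial durations (s)
    max_dur_rotate: float = 6.0
    max_dur_move: float = 15.0
    max_dur_chase: float = 12.0
    align_tol: float = 2.0
    # target placement (m from start)
    target_min_dist: float = 10.0
    target_max_dist: float = 18.0
    # noise scales at skill = 0
    rot_noise_dynamic: float = 60.0  # deg/step heading noise, chase tasks
    rot_noise_static: float = 2.0  # deg/step heading noise, static tasks
    aim_bearing_noise: float = 12.0  # deg, aim offset on static rotations
    aim_pos_noise: float = 1.5  # m, stop offset on static translations
    mem_bearing_noise: float = 40.0  # deg, remembered bearing (RFM)
    mem_pos_noise: float = 6.0  # m, remembered position (MFM)
    map_bearing_noise: float = 30.0  # deg, map-derived bearing (RWM)
    map_pos_noise: float = 5.0  # m, map-derived position (MWM)
    map_read_noise: float = 3.0  # m, continuous map reading (CWM)
    # navigation phase
    wrong_turn_scale: float = 0.15
    explore_wrong_turn: float = 0.3
    explore_decay: float = 0.6
    trigger_mu: float = 24.15
    trigger_decay: float = 0.52
    n_learning_blocks: int = 3


# ---------------------------------------------------------------------------
# simple-task controllers


def check_rotation_only(trial: TrialLog, tol: float = 1e-9) -> None:
    """Raise if a rotation-only task's trajectory contains translation."""
    if trial.task in ROTATION_ONLY:
        disp = np.abs(np.diff(trial.xy, axis=0)).max() if len(trial.poses) > 1 else 0.0
        if disp > tol:
            raise ValueError(
                f"translation requested in rotation-only task {trial.task} "
                f"(max step displacement {disp:.3g} m)"
            )


def _wrap180(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def _pick_target(field: SphereField, start: tuple, cfg: SimConfig, rng) -> int:
    """Target sphere at a workable distance from the start position."""
    d = np.hypot(field.positions[:, 0] - start[0], field.positions[:, 1] - start[1])
    ok = np.flatnonzero((d >= cfg.target_min_dist) & (d <= cfg.target_max_dist))
    if len(ok) == 0:
        return int(np.argmin(np.abs(d - 0.5 * (cfg.target_min_dist + cfg.target_max_dist))))
    return int(rng.choice(ok))


def simulate_simple_task(
    task: TaskSpec | str,
    agent: AgentParams,
    field: SphereField | None = None,
    config: SimConfig = SimConfig(),
    rng: np.random.Generator | int | None = None,
    participant: str = "sim",
    block: int = 1,
) -> TrialLog:
    """Simulate one trial of one simple task and return its TrialLog.

    The agent starts at the field centre.  Rotation tasks turn towards a
    (possibly map-derived or remembered) bearing and press the trigger
    when aligned; move tasks head for a (possibly misjudged) point and
    stop one catchment offset short of it; chase tasks pursue the moving
    target until interception.  All logs are uniform in time at
    ``config.dt`` and end with exactly one completion trigger.
    """
    if isinstance(task, str):
        task = TASKS[task]
    rng = np.random.default_rng(rng)
    if field is None:
        field = make_sphere_field(
            config.n_spheres, config.field_side, config.sphere_min_sep, rng=rng
        )
    start = (field.side / 2.0, field.side / 2.0)
    tid = _pick_target(field, start, config, rng)
    target = field.positions[tid]

    if task.code in ROTATION_ONLY:
        poses, spheres = _run_rotation_task(task, agent, field, tid, start, config, rng)
    elif task.dynamic:
        poses, spheres = _run_chase_task(task, agent, field, tid, start, config, rng)
    else:
        poses, spheres = _run_move_task(task, agent, field, tid, start, config, rng)

    return TrialLog(
        participant=participant,
        phase="simple",
        task=task.code,
        block=block,
        poses=poses,
        sphere_series=spheres,
        target_ids=frozenset({tid}),
        triggers=np.array([poses[-1, 0]]),
    )


def _static_sphere_series(field: SphereField, tid: int, t_end: float) -> dict[int, np.ndarray]:
    x, y = field.positions[tid]
    return {tid: np.array([[0.0, x, y], [t_end, x, y]])}


def _run_rotation_task(task, agent, field, tid, start, cfg, rng):
    tx, ty = field.positions[tid]
    true_bearing = math.degrees(math.atan2(ty - start[1], tx - start[0])) % 360.0
    est_bearing = true_bearing + rng.normal(
        0.0, cfg.aim_bearing_noise * (1.0 - agent.aim_precision)
    )
    if task.code == "RWM":
        est_bearing += rng.normal(0.0, cfg.map_bearing_noise * (1.0 - agent.map_skill))
    elif task.code == "RFM":
        est_bearing += rng.normal(0.0, cfg.mem_bearing_noise * (1.0 - agent.memory_fidelity))
    yaw = rng.uniform(0.0, 360.0)
    dt = cfg.dt
    max_turn = agent.turn_rate * dt
    noise_sd = cfg.rot_noise_static * (1.0 - agent.motor_skill)
    n_max = int(cfg.max_dur_rotate / dt)
    rows = [(0.0, start[0], start[1], yaw)]
    for i in range(1, n_max + 1):
        err = _wrap180(est_bearing - yaw)
        turn = max(-max_turn, min(max_turn, err))
        if noise_sd > 0:
            turn += rng.normal(0.0, noise_sd)
        yaw = (yaw + turn) % 360.0
        rows.append((i * dt, start[0], start[1], yaw))
        if abs(_wrap180(est_bearing - yaw)) < cfg.align_tol:
            break
    poses = np.array(rows)
    return poses, _static_sphere_series(field, tid, poses[-1, 0])


def _run_move_task(task, agent, field, tid, start, cfg, rng):
    tx, ty = field.positions[tid]
    est = np.array([tx, ty], dtype=float)
    est += rng.normal(0.0, cfg.aim_pos_noise * (1.0 - agent.aim_precision), size=2)
    if task.code == "MWM":
        est += rng.normal(0.0, cfg.map_pos_noise * (1.0 - agent.map_skill), size=2)
    elif task.code == "MFM":
        est += rng.normal(0.0, cfg.mem_pos_noise * (1.0 - agent.memory_fidelity), size=2)
    x, y = start
    if task.code == "MWM":
        yaw = rng.uniform(0.0, 360.0)  # target not identifiable first-person
    else:
        yaw = math.degrees(math.atan2(ty - y, tx - x)) % 360.0
    dt = cfg.dt
    max_turn = agent.turn_rate * dt
    noise_sd = cfg.rot_noise_static * (1.0 - agent.motor_skill)
    step_max = agent.speed * dt
    n_max = int(cfg.max_dur_move / dt)
    min_step = 1e-2  # skip sub-centimeter final corrections
    rows = [(0.0, x, y, yaw)]
    for i in range(1, n_max + 1):
        bearing = math.degrees(math.atan2(est[1] - y, est[0] - x)) % 360.0
        err = _wrap180(bearing - yaw)
        turn = max(-max_turn, min(max_turn, err))
        if noise_sd > 0:
            turn += rng.normal(0.0, noise_sd)
        yaw = (yaw + turn) % 360.0
        remaining = math.hypot(est[0] - x, est[1] - y) - cfg.catchment_offset
        if remaining >= min_step and abs(err) < 90.0:
            step = min(step_max, remaining)
            rad = math.radians(yaw)
            x += step * math.cos(rad)
            y += step * math.sin(rad)
        rows.append((i * dt, x, y, yaw))
        if math.hypot(est[0] - x, est[1] - y) - cfg.catchment_offset < min_step:
            break
    poses = np.array(rows)
    return poses, _static_sphere_series(field, tid, poses[-1, 0])


def _run_chase_task(task, agent, field, tid, start, cfg, rng):
    # Only the pursued target's motion influences behaviour and scoring;
    # distractor spheres are scenery and are logged at rest unless full
    # distractor motion is requested (cfg.log_distractor_motion).
    dt = cfg.dt
    n_max = int(cfg.max_dur_chase / dt)
    side = field.side
    x, y = start
    sx, sy = field.positions[tid]
    wx, wy = rng.uniform(0.0, side, size=2)
    yaw = rng.uniform(0.0, 360.0)
    max_turn = agent.turn_rate * dt
    noise_sd = cfg.rot_noise_dynamic * (1.0 - agent.motor_skill)
    read_sd = cfg.map_read_noise * (1.0 - agent.map_skill) if task.code == "CWM" else 0.0
    step_max = agent.speed * dt
    sphere_step = cfg.sphere_speed * dt
    rows = [(0.0, x, y, yaw)]
    target_rows = [(0.0, sx, sy)]
    for i in range(1, n_max + 1):
        ox, oy = sx, sy
        if read_sd > 0:
            ox += rng.normal(0.0, read_sd)
            oy += rng.normal(0.0, read_sd)
        bearing = math.degrees(math.atan2(oy - y, ox - x)) % 360.0
        err = _wrap180(bearing - yaw)
        turn = max(-max_turn, min(max_turn, err))
        if noise_sd > 0:
            turn += rng.normal(0.0, noise_sd)
        yaw = (yaw + turn) % 360.0
        rad = math.radians(yaw)
        x = min(max(x + step_max * math.cos(rad), 0.0), side)
        y = min(max(y + step_max * math.sin(rad), 0.0), side)
        # random-waypoint step of the pursued sphere
        dwx, dwy = wx - sx, wy - sy
        dist = math.hypot(dwx, dwy)
        if dist <= sphere_step:
            sx, sy = wx, wy
            wx, wy = rng.uniform(0.0, side, size=2)
        else:
            sx += sphere_step * dwx / dist
            sy += sphere_step * dwy / dist
        rows.append((i * dt, x, y, yaw))
        target_rows.append((i * dt, sx, sy))
        if math.hypot(sx - x, sy - y) <= cfg.intercept_radius:
            break
    poses = np.array(rows)
    t_end = poses[-1, 0]
    spheres = {tid: np.array(target_rows)}
    if cfg.log_distractor_motion:
        others = [s for s in range(len(field.positions)) if s != tid]
        motion = simulate_sphere_motion(field, t_end, dt, cfg.sphere_speed, rng=rng)
        for s in others:
            spheres[s] = np.column_stack([poses[:, 0], motion[: len(poses), s]])
    else:
        for s in range(len(field.positions)):
            if s != tid:
                px, py = field.positions[s]
                spheres[s] = np.array([[0.0, px, py], [t_end, px, py]])
    return poses, spheres


def simulate_session(
    agent: AgentParams,
    config: SimConfig = SimConfig(),
    rng: np.random.Generator | int | None = None,
    participant: str = "sim",
) -> list[TrialLog]:
    """All simple-task trials of one agent: eight tasks in random order in
    each of ``config.n_blocks`` blocks, spheres re-randomised per task."""
    rng = np.random.default_rng(rng)
    logs = []
    for block in range(1, config.n_blocks + 1):
        order = rng.permutation(len(TASK_CODES))
        for k in order:
            logs.append(
                simulate_simple_task(
                    TASK_CODES[k], agent, None, config, rng, participant=participant, block=block
                )
            )
    return logs


# ---------------------------------------------------------------------------
# road network and navigation phase


@dataclass
class RoadNetwork:
    """Connected road network with node coordinates, edge lengths and six goals."""

    graph: nx.Graph
    goals: list  # [(goal_id, node_id)] exactly six

    def __post_init__(self) -> None:
        if len(self.goals) != 6:
            raise ValueError(f"exactly six goals required, got {len(self.goals)}")
        if not nx.is_connected(self.graph):
            raise ValueError("road network must be connected")
        for a, b, data in self.graph.edges(data=True):
            euclid = math.dist(self.graph.nodes[a]["pos"], self.graph.nodes[b]["pos"])
            if data["length"] < euclid - 1e-6:
                raise ValueError(f"edge ({a}, {b}) shorter than straight-line distance")
        for _, node in self.goals:
            if node not in self.graph:
                raise ValueError(f"goal node {node!r} not in network")
        self._next_hop: dict | None = None

    def node_pos(self, node) -> tuple:
        return tuple(self.graph.nodes[node]["pos"])

    def _ensure_tables(self) -> None:
        if self._next_hop is None:
            self._next_hop = {}
            self._goal_dist = {}
            for tgt in {n for _, n in self.goals}:
                dist, paths = nx.single_source_dijkstra(self.graph, tgt, weight="length")
                self._next_hop[tgt] = {u: p[-2] for u, p in paths.items() if len(p) > 1}
                self._goal_dist[tgt] = dist

    def next_hop(self, node, goal):
        """First edge of a shortest path from node to goal (cached)."""
        self._ensure_tables()
        return self._next_hop[goal][node]

    def detour_neighbors(self, node, goal) -> list:
        """Neighbors through which the route to ``goal`` becomes strictly
        longer (true wrong turns, not alternative shortest paths)."""
        self._ensure_tables()
        d = self._goal_dist[goal]
        best = d[node]
        return [
            v
            for v in self.graph[node]
            if self.graph[node][v]["length"] + d[v] > best + 1e-9
        ]

    @classmethod
    def from_csv(cls, nodes_path, edges_path, goals=None) -> "RoadNetwork":
        """Build from nodes.csv (id,x,y) and edges.csv (a,b,length)."""
        import pandas as pd

        nodes = pd.read_csv(nodes_path)
        edges = pd.read_csv(edges_path)
        g = nx.Graph()
        for _, row in nodes.iterrows():
            g.add_node(int(row["id"]), pos=(float(row["x"]), float(row["y"])))
        for _, row in edges.iterrows():
            g.add_edge(int(row["a"]), int(row["b"]), length=float(row["length"]))
        if goals is None:
            goals = [(i + 1, int(nodes["id"].iloc[i])) for i in range(6)]
        return cls(graph=g, goals=list(goals))


def make_grid_network(n: int = 7, spacing: float = 35.0) -> RoadNetwork:
    """An n x n street grid with straight edges and six spread-out goals."""
    g = nx.Graph()
    for i in range(n):
        for j in range(n):
            g.add_node(i * n + j, pos=(i * spacing, j * spacing))
    for i in range(n):
        for j in range(n):
            u = i * n + j
            if i + 1 < n:
                g.add_edge(u, (i + 1) * n + j, length=spacing)
            if j + 1 < n:
                g.add_edge(u, u + 1, length=spacing)
    corner = n - 1
    goal_nodes = [0, corner, n * n - 1, n * (n - 1), (n // 2) * n + n // 2, corner * n // 2]
    goal_nodes = list(dict.fromkeys(goal_nodes))[:6]
    k = 0
    while len(goal_nodes) < 6:
        if k not in goal_nodes:
            goal_nodes.append(k)
        k += 1
    return RoadNetwork(graph=g, goals=[(i + 1, node) for i, node in enumerate(goal_nodes)])


def simulate_navigation(
    network: RoadNetwork,
    agent: AgentParams,
    n_learning_blocks: int = 3,
    rng: np.random.Generator | int | None = None,
    config: SimConfig = SimConfig(),
    participant: str = "sim",
) -> tuple[list[TrialLog], dict[int, int]]:
    """Multi-block navigation: learning blocks with random goal orders and
    guidance-arrow presses, then one testing block with a fixed order.

    At every junction the agent takes the shortest-path edge with
    probability 1 - p_wrong and a random wrong edge otherwise (then
    recovers).  p_wrong = wrong_turn_scale * (1 - nav_skill), plus an
    exploration surcharge that decays across learning blocks.  Arrow
    presses per learning block are Poisson with mean
    trigger_mu * (1.5 - nav_skill) * trigger_decay^(block-1), spread over
    the block's six trials; the testing block has no presses.

    Returns the trial logs and the per-block press counts.
    """
    rng = np.random.default_rng(rng)
    logs: list[TrialLog] = []
    counts: dict[int, int] = {}
    goal_ids = [gid for gid, _ in network.goals]
    goal_node = dict(network.goals)
    current = network.goals[0][1]
    base_wrong = config.wrong_turn_scale * (1.0 - agent.nav_skill)
    for block in range(1, n_learning_blocks + 2):
        testing = block == n_learning_blocks + 1
        if testing:
            order, p_wrong, mu = goal_ids, base_wrong, 0.0
        else:
            order = [goal_ids[i] for i in rng.permutation(len(goal_ids))]
            p_wrong = min(
                0.9, base_wrong + config.explore_wrong_turn * config.explore_decay ** (block - 1)
            )
            mu = (
                config.trigger_mu
                * (1.5 - agent.nav_skill)
                * config.trigger_decay ** (block - 1)
            )
        n_presses = 0
        for gid in order:
            goal = goal_node[gid]
            if goal == current:
                continue
            nodes = [current]
            walked = 0.0
            # the walk has positive drift toward the goal for any
            # p_wrong < 0.5, so this cap only guards degenerate configs
            for _ in range(20_000):
                if current == goal:
                    break
                correct = network.next_hop(current, goal)
                detours = network.detour_neighbors(current, goal)
                if detours and rng.random() < p_wrong:
                    nxt = detours[rng.integers(len(detours))]
                else:
                    nxt = correct
                walked += network.graph[current][nxt]["length"]
                nodes.append(nxt)
                current = nxt
            else:
                raise RuntimeError(f"goal {gid} unreachable within step limit")
            poses = _nodes_to_poses(network, nodes, agent.speed)
            trig = np.empty(0)
            if not testing:
                k = rng.poisson(mu / len(order))
                n_presses += int(k)
                if k:
                    trig = np.sort(rng.uniform(0.0, poses[-1, 0], size=k))
            logs.append(
                TrialLog(
                    participant=participant,
                    phase="navigation",
                    task=str(gid),
                    block=block,
                    poses=poses,
                    triggers=trig,
                )
            )
        if not testing:
            counts[block] = n_presses
    return logs, counts


def _nodes_to_poses(network: RoadNetwork, nodes: list, speed: float) -> np.ndarray:
    pts = np.array([network.node_pos(u) for u in nodes], dtype=float)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg) / speed])
    yaw = np.degrees(np.arctan2(np.diff(pts[:, 1]), np.diff(pts[:, 0]))) % 360.0
    yaw = np.concatenate([yaw, yaw[-1:]]) if len(yaw) else np.zeros(len(pts))
    return np.column_stack([t, pts, yaw])


# ---------------------------------------------------------------------------
# direct factor-model scores (for factor-recovery experiments)


def make_factor_scores(
    n: int,
    loadings: np.ndarray,
    rng: np.random.Generator | int | None = None,
    factor_corr: np.ndarray | None = None,
    standardize: bool = True,
) -> np.ndarray:
    """Draw an n x p score matrix from a common-factor model.

    ``loadings`` is p x m; unique variances are 1 - communality per row
    (rows must have communality <= 1).  Used to plant a known factor
    structure directly at the score level.
    """
    rng = np.random.default_rng(rng)
    L = np.asarray(loadings, dtype=float)
    p, m = L.shape
    if factor_corr is None:
        F = rng.standard_normal((n, m))
    else:
        F = rng.multivariate_normal(np.zeros(m), factor_corr, size=n)
    h = np.sum((L @ (factor_corr if factor_corr is not None else np.eye(m))) * L, axis=1)
    if np.any(h > 1.0 + 1e-9):
        raise ValueError("row communalities exceed 1")
    E = rng.standard_normal((n, p)) * np.sqrt(np.maximum(0.0, 1.0 - h))
    Z = F @ L.T + E
    if standardize:
        Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
    return Z
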