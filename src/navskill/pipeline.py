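"""Orchestration: simulate -> ingest -> score -> factor-analyse -> infer.

One :class:`RunConfig` drives a reproducible run.  All randomness flows
from a single root seed through named substreams (population, per-agent
trials, permutation test, rotation starts), so stages are individually
reproducible and re-runnable from persisted intermediates.  Every run
writes a manifest with the config hash, seed and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from navskill import __version__, inference, refa as refa_mod, scoring, trajio, world
from navskill._rng import substream

__all__ = [
    "RunConfig",
    "StudyResults",
    "simulate_study",
    "score_study",
    "simulate_and_score",
    "run_full_analysis",
]

log = logging.getLogger("navskill")


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    seed: int = 0
    out_dir: str = "navskill_run"
    n_agents: int = 20
    logs_path: str | None = None  # score existing logs instead of simulating
    nodes_path: str | None = None  # road network CSV pair; default grid if None
    edges_path: str | None = None
    dt: float = 0.1
    catchment_offset: float = 4.0
    n_factors: int | None = None
    lam: float | None = None
    refa_alpha: float = 0.05
    n_permutations: int = 500
    geomin_eps: float = 0.01
    n_starts: int = 100
    regression_method: str = "hc3"
    loadings: list | None = None  # latent loading matrix rows (motor, memory, map, nav)
    sim: dict = field(default_factory=dict)  # overrides for world.SimConfig

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("logs_path", "nodes_path", "edges_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")

    def sim_config(self) -> world.SimConfig:
        return dataclasses.replace(
            world.SimConfig(dt=self.dt, catchment_offset=self.catchment_offset), **self.sim
        )

    def loading_matrix(self) -> np.ndarray:
        if self.loadings is None:
            return world.DEFAULT_LOADINGS
        return np.asarray(self.loadings, dtype=float)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class StudyResults:
    """Results bundle of one full run."""

    z_matrix: pd.DataFrame
    nav: pd.DataFrame
    scores: pd.DataFrame
    refa_results: refa_mod.REFAResults | None
    confirmatory: pd.DataFrame | None
    exploratory: pd.DataFrame | None
    manifest: dict


# ---------------------------------------------------------------------------
# simulation and scoring stages


def simulate_study(
    n_agents: int,
    seed: int,
    sim_config: world.SimConfig = world.SimConfig(),
    loadings: np.ndarray = world.DEFAULT_LOADINGS,
    network: world.RoadNetwork | None = None,
) -> tuple[list[trajio.TrialLog], world.RoadNetwork]:
    """Simulate simple-task sessions and navigation for a population."""
    if network is None:
        network = world.make_grid_network()
    agents = world.make_population(n_agents, loadings, substream(seed, "population"))
    logs: list[trajio.TrialLog] = []
    for i, agent in enumerate(agents):
        pid = f"P{i:03d}"
        logs += world.simulate_session(
            agent, sim_config, substream(seed, f"simple/{i}"), participant=pid
        )
        nav_logs, _ = world.simulate_navigation(
            network,
            agent,
            sim_config.n_learning_blocks,
            substream(seed, f"nav/{i}"),
            sim_config,
            participant=pid,
        )
        logs += nav_logs
    return logs, network


def score_study(
    logs: list[trajio.TrialLog],
    network: world.RoadNetwork,
    scoring_config: scoring.ScoringConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Score all trials: per-trial table, z-matrix, and navigation frame."""
    cfg = scoring_config or scoring.ScoringConfig()
    rows = []
    nav_acc: dict[str, dict] = {}
    goal_node = dict(network.goals)
    n_learning = max(
        (lg.block for lg in logs if lg.phase == "navigation"), default=1
    ) - 1
    for lg in logs:
        if lg.phase == "simple":
            ts = scoring.score_trial(lg, cfg)
            rows.append(
                {
                    "participant": lg.participant,
                    "task": lg.task,
                    "block": lg.block,
                    "error": ts.combined,
                    "time": ts.time,
                }
            )
        elif lg.phase == "navigation":
            acc = nav_acc.setdefault(
                lg.participant,
                {"ratios": [], **{f"presses_block{b}": 0 for b in range(1, n_learning + 1)}},
            )
            if lg.block == n_learning + 1:  # testing block
                start = _nearest_node(network, lg.xy[0])
                d_r = scoring.shortest_route_distance(network, start, goal_node[int(lg.task)])
                acc["ratios"].append(scoring.navigation_distance_ratio(lg, d_r))
            else:
                acc[f"presses_block{lg.block}"] += len(lg.triggers)
    scores = pd.DataFrame(rows)
    z = scoring.aggregate_and_standardize(scores) if len(scores) else pd.DataFrame()
    nav_rows = []
    for pid, acc in sorted(nav_acc.items()):
        row = {"participant": pid, "mean_ratio": float(np.mean(acc["ratios"]))}
        row.update({k: v for k, v in acc.items() if k.startswith("presses")})
        nav_rows.append(row)
    nav = pd.DataFrame(nav_rows).set_index("participant") if nav_rows else pd.DataFrame()
    if len(z) and len(nav):
        nav = nav.loc[z.index]
    return scores, z, nav


def _nearest_node(network: world.RoadNetwork, xy) -> int:
    best, best_d = None, np.inf
    for node in network.graph.nodes:
        d = float(np.hypot(*(np.asarray(network.node_pos(node)) - xy)))
        if d < best_d:
            best, best_d = node, d
    return best


def simulate_and_score(
    n_agents: int = 20,
    seed: int = 0,
    sim_config: world.SimConfig = world.SimConfig(),
    loadings: np.ndarray = world.DEFAULT_LOADINGS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a population and return (z_matrix, nav frame) in memory."""
    logs, network = simulate_study(n_agents, seed, sim_config, loadings)
    _, z, nav = score_study(logs, network)
    return z, nav


def dynamic_recovery_experiment(
    n_replicates: int = 100,
    n_agents: int = 200,
    seed: int = 0,
    sim_config: world.SimConfig = world.SimConfig(),
    loadings: np.ndarray = world.DEFAULT_LOADINGS,
) -> pd.DataFrame:
    """Parameter-recovery experiment over replicate synthetic worlds.

    Each replicate simulates a fresh population (planted latent
    correlation 0.6 between dynamic-task skill and navigation ability),
    scores it, and runs the confirmatory category regressions.  Returns a
    frame with one row per replicate x composite (columns: replicate,
    factor, chi2, beta, p_value) with the Šidák level in ``attrs``.
    """
    rng = substream(seed, "recovery")
    frames = []
    level = None
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        z, nav = simulate_and_score(n_agents, rep_seed, sim_config, loadings)
        tab = inference.confirmatory_analysis(z, nav["mean_ratio"])
        tab.insert(0, "replicate", rep)
        level = tab.attrs["sidak_level"]
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["sidak_level"] = level
    return out


# ---------------------------------------------------------------------------
# full pipeline


def run_full_analysis(config: RunConfig) -> StudyResults:
    """Run every stage and persist all intermediate artifacts.

    Deterministic given ``config.seed``; the manifest records the config
    hash, seed and versions.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "versions": {
            "navskill": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    timings = manifest["stages"]

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        return t0

    def done(name, t0):
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", name, timings[name])

    # --- simulate or ingest -------------------------------------------------
    t0 = stage("simulate")
    if config.nodes_path:
        network = world.RoadNetwork.from_csv(config.nodes_path, config.edges_path)
    else:
        network = world.make_grid_network()
    try:
        if config.logs_path:
            logs = trajio.read_trial_logs(config.logs_path)
        else:
            logs, network = simulate_study(
                config.n_agents,
                config.seed,
                config.sim_config(),
                config.loading_matrix(),
                network,
            )
            trajio.write_trial_logs(logs, out / "logs.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    done("simulate", t0)

    # --- score --------------------------------------------------------------
    t0 = stage("score")
    try:
        cfg = scoring.ScoringConfig(catchment_offset=config.catchment_offset, dt=config.dt)
        scores, z, nav = score_study(logs, network, cfg)
    except Exception as exc:
        raise RuntimeError(f"stage 'score' failed: {exc}") from exc
    scores.to_csv(out / "scores.csv", index=False)
    z.to_csv(out / "z_matrix.csv")
    z.join(nav).to_csv(out / "score_matrix.csv")
    done("score", t0)

    # --- refa ---------------------------------------------------------------
    t0 = stage("refa")
    try:
        model = refa_mod.REFA(
            z,
            n_factors=config.n_factors,
            lam=config.lam,
            geomin_eps=config.geomin_eps,
            n_starts=config.n_starts,
            n_permutations=config.n_permutations,
            alpha=config.refa_alpha,
        )
        results = model.fit(seed=int(substream(config.seed, "refa").integers(2**31)))
    except Exception as exc:
        raise RuntimeError(f"stage 'refa' failed: {exc}") from exc
    rep = results.communality_report()
    rep.as_series(results.model.task_names).to_csv(out / "communalities.csv")
    n_sets = len(results.rotation_sets) if results.rotation_sets else 0
    for s in range(n_sets):
        results.loadings_frame(s).to_csv(out / f"loadings_set{s + 1}.csv")
    (out / "refa_summary.txt").write_text(results.summary())
    done("refa", t0)

    # --- infer --------------------------------------------------------------
    t0 = stage("infer")
    try:
        conf = inference.confirmatory_analysis(
            z, nav["mean_ratio"], method=config.regression_method
        )
        expl = inference.exploratory_analysis(
            results, nav["mean_ratio"], method=config.regression_method
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'infer' failed: {exc}") from exc
    table = pd.concat([conf, expl], ignore_index=True)
    table.to_csv(out / "regressions.csv", index=False)
    done("infer", t0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return StudyResults(
        z_matrix=z,
        nav=nav,
        scores=scores,
        refa_results=results,
        confirmatory=conf,
        exploratory=expl,
        manifest=manifest,
    )
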