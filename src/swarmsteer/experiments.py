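"""Success metric, parametric sweeps, and digital-shadow validation utilities.

The steering performance of a run is the percentage of the released particles
that exit through the goal outlet. Parametric sweeps repeat seeded runs
(10 per parameter value by default) over fluid velocity, gradient limit or
seeding mode and report the mean and sample standard deviation of that
percentage. Particles still in transit when the simulated-time cap expires
count as failures.

The validation utilities mirror the computational side of the bench
comparison against a real electromagnet workspace: the semi-static time to
translate the swarm 1 mm under a uniform gradient in an open workspace (no
vessel, no flow), the average percentage difference between paired
simulated/measured times, and the binarize-plus-center-of-mass reduction of
grayscale camera frames used to measure swarm displacement.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import SeedSpec, SimConfig, run_simulation, semi_static_velocity
from .flowfield import (
    ConstantFlow,
    FlowFieldConfig,
    build_lookup_table,
    solve_network_flow,
)
from .geometry import NetworkGraph, build_comb_network, network_to_polygon
from .magnetics import MagneticParams, limit_gradient, magnetic_force
from .runlog import RunLog, read_log, write_log, write_outcomes_csv  # noqa: F401  (re-export)
from .steering import WaypointAutopilot

__all__ = [
    "ExperimentSetup",
    "SweepResult",
    "StationarySwarmError",
    "NoParticlesError",
    "success_metric",
    "run_single",
    "run_sweep",
    "sweep_seeds",
    "time_to_travel",
    "percentage_difference",
    "binarize_and_centroid",
    "write_summary",
    "read_summary",
    "RunLog",
    "read_log",
    "write_log",
]


class StationarySwarmError(RuntimeError):
    """Zero applied force: the swarm never covers the requested distance."""


class NoParticlesError(ValueError):
    """Binarized frame contains no foreground pixels."""


def success_metric(log: RunLog, goal: str) -> float:
    """Percentage of particles whose exit outlet is the goal."""
    if log.outcomes is None:
        raise ValueError("log has no outcomes")
    hits = int((log.outcomes["exit_outlet"] == goal).sum())
    return 100.0 * hits / len(log.outcomes)


@dataclass
class ExperimentSetup:
    """Bundle of everything a steering run needs, with platform defaults."""

    graph: NetworkGraph = field(default_factory=build_comb_network)
    sim_config: SimConfig = field(default_factory=SimConfig)
    magnetic: MagneticParams = field(default_factory=MagneticParams)
    flow_config: FlowFieldConfig = field(default_factory=FlowFieldConfig)
    seed_spec: SeedSpec = field(default_factory=SeedSpec)

    def __post_init__(self) -> None:
        self._polygon = network_to_polygon(self.graph)
        self._flow_cache: dict[float, object] = {}

    @property
    def polygon(self):
        return self._polygon

    def flow_table(self):
        """Lookup table for the current flow config (cached per velocity)."""
        v = self.flow_config.inlet_central_velocity
        if v not in self._flow_cache:
            solution = solve_network_flow(self.graph, self.flow_config)
            self._flow_cache[v] = build_lookup_table(
                self.graph, solution, lumen=self._polygon
            )
        return self._flow_cache[v]


def _default_policy_factory(setup: ExperimentSetup):
    return WaypointAutopilot(setup.graph, setup.graph.goal_outlet)


def run_single(setup: ExperimentSetup, seed: int, policy_factory=None) -> RunLog:
    """One seeded steering run with the setup's parameters."""
    policy = (policy_factory or _default_policy_factory)(setup)
    config = replace(setup.sim_config, rng_seed=int(seed))
    return run_simulation(
        config,
        setup.graph,
        setup.flow_table(),
        policy,
        setup.seed_spec,
        params=setup.magnetic,
        polygon=setup.polygon,
    )


def sweep_seeds(master_seed: int, repeats: int) -> list[int]:
    """Deterministic per-run seeds derived from one master seed (< 2^31)."""
    return [int(s) for s in np.random.SeedSequence(master_seed).generate_state(repeats) % (2**31)]


@dataclass
class SweepResult:
    """Per-parameter-value success statistics over repeated seeded runs."""

    parameter: str
    rows: list[tuple[float | str, float, float, int]]  # (value, mean %, SD %, repeats)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["parameter", "mean_pct", "sd_pct", "repeats"]
        )

    def mean_for(self, value) -> float:
        for v, mean, _, _ in self.rows:
            if v == value:
                return mean
        raise KeyError(value)


_SWEEPABLE = ("flow_velocity", "gradient_limit", "seed_mode")


def _apply_parameter(setup: ExperimentSetup, parameter: str, value) -> ExperimentSetup:
    if parameter == "flow_velocity":
        new = replace(setup.flow_config, inlet_central_velocity=float(value))
        setup = ExperimentSetup(
            setup.graph, setup.sim_config, setup.magnetic, new, setup.seed_spec
        )
    elif parameter == "gradient_limit":
        new_cfg = replace(setup.sim_config, gradient_limit_mT_m=float(value))
        setup = ExperimentSetup(
            setup.graph, new_cfg, setup.magnetic, setup.flow_config, setup.seed_spec
        )
    elif parameter == "seed_mode":
        new_seed = replace(setup.seed_spec, mode=str(value))
        setup = ExperimentSetup(
            setup.graph, setup.sim_config, setup.magnetic, setup.flow_config, new_seed
        )
    else:
        raise ValueError(f"unknown sweep parameter {parameter!r}; expected one of {_SWEEPABLE}")
    return setup


def run_sweep(
    parameter: str,
    values,
    setup: ExperimentSetup | None = None,
    policy_factory=None,
    repeats: int = 10,
    seeds: list[int] | None = None,
) -> SweepResult:
    """Repeat seeded runs for each parameter value; report mean and sample SD.

    The same seed list is reused across values so the comparison is paired.
    """
    setup = setup if setup is not None else ExperimentSetup()
    if seeds is None:
        seeds = sweep_seeds(0, repeats)
    if len(seeds) != repeats:
        raise ValueError("len(seeds) must equal repeats")
    if repeats == 1:
        warnings.warn("repeats=1: standard deviation reported as 0")
    rows = []
    for value in values:
        cur = _apply_parameter(setup, parameter, value)
        scores = [
            success_metric(run_single(cur, seed, policy_factory), cur.graph.goal_outlet)
            for seed in seeds
        ]
        sd = float(np.std(scores, ddof=1)) if repeats > 1 else 0.0
        rows.append((value, float(np.mean(scores)), sd, repeats))
    return SweepResult(parameter, rows)


def time_to_travel(
    params: MagneticParams,
    gradient_mT_m: float,
    distance: float = 1e-3,
    viscosity: float = 1e-3,
    d_drag: float | None = None,
    method: str = "closed_form",
    dt: float = 0.05 / 25,
) -> float:
    """Time (s) for the swarm to travel ``distance`` under a uniform gradient.

    Open-workspace conditions: no vessel, no flow. The closed form is
    distance / |v_p| with v_p the semi-static velocity; the simulated method
    integrates minor steps and interpolates the crossing fraction (the two
    agree to rounding because the velocity is constant).
    """
    if gradient_mT_m <= 0:
        raise StationarySwarmError("zero gradient: the swarm remains stationary")
    d_drag = d_drag if d_drag is not None else params.d
    cmd = limit_gradient(np.array([1.0, 0.0]), gradient_mT_m)
    F = magnetic_force(params, cmd)
    v = semi_static_velocity(F, np.zeros(2), viscosity, d_drag)
    speed = float(np.linalg.norm(v))
    if speed == 0.0:
        raise StationarySwarmError("zero force: the swarm remains stationary")
    if method == "closed_form":
        return distance / speed
    if method == "simulated":
        flow = ConstantFlow((0.0, 0.0))
        pos = np.zeros(2)
        t = 0.0
        while True:
            step = semi_static_velocity(F, flow.sample(pos), viscosity, d_drag) * dt
            if np.linalg.norm(pos + step) >= distance:
                remaining = distance - float(np.linalg.norm(pos))
                return t + remaining / speed
            pos = pos + step
            t += dt
    raise ValueError(f"unknown method {method!r}")


def percentage_difference(sim, exp) -> float:
    """Mean over pairs of 100 |sim - exp| / exp."""
    sim = np.asarray(sim, float)
    exp = np.asarray(exp, float)
    if sim.shape != exp.shape:
        raise ValueError("sim and exp must have equal length")
    if np.any(exp <= 0):
        raise ValueError("experimental values must be > 0")
    return float(np.mean(100.0 * np.abs(sim - exp) / exp))


def binarize_and_centroid(
    image: np.ndarray,
    threshold: float | None = None,
    px_per_mm: float | None = None,
) -> np.ndarray:
    """Center of mass of the dark-particle foreground of a grayscale frame.

    Pixels strictly below the threshold (Otsu's method when not given) form
    the foreground. Returns (x, y) in pixel coordinates (x = column, y = row),
    or in mm when ``px_per_mm`` is supplied.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise NoParticlesError("empty image")
    if threshold is None:
        from skimage.filters import threshold_otsu

        try:
            threshold = threshold_otsu(image)
        except ValueError as exc:  # uniform image
            raise NoParticlesError("uniform image: no foreground") from exc
    mask = image < threshold
    if not mask.any():
        raise NoParticlesError("no foreground pixels below the threshold")
    rows, cols = np.nonzero(mask)
    centroid = np.array([cols.mean(), rows.mean()])
    if px_per_mm is not None:
        centroid = centroid / px_per_mm
    return centroid


def write_summary(result: SweepResult, path) -> None:
    result.to_frame().to_csv(path, index=False)


def read_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["parameter", "mean_pct", "sd_pct", "repeats"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df
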