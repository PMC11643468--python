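"""Two-rate semi-static particle dynamics.

The integrator mirrors the platform's real-time architecture: a major loop
(MaL) at 20 Hz reads one steering input, converts it to a gradient command and
logs the state; within each major step the minor loop (MiL) advances the
physics 25 times with a 0.05/25 = 0.002 s timestep, holding forces constant.

Inertia is eliminated by the semi-static assumption: within one minor step the
Stokes drag -3 pi eta d (v_p - v_f) instantaneously balances the applied
force, so the particle velocity is

    v_p = v_f + F / (3 pi eta d)

Particles are advected independently (they share the chain force model but do
not interact). A proposed step that crosses an outlet gate retires the
particle with that outlet id; a step that leaves the lumen is resolved by
bisecting to the wall, then reflecting the residual displacement and velocity
about the wall tangent (elastic for wall friction mu = 0; the tangential
component is attenuated by (1 - mu) otherwise). A particle trapped in a
corner after 4 reflection attempts is marked stuck at the wall.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import LumenPolygon, NetworkGraph, crossed_outlets, network_to_polygon
from .magnetics import GradientCommand, MagneticParams, limit_gradient, magnetic_force
from .runlog import STATUS_NAMES, MajorRecord, RunLog

__all__ = [
    "ACTIVE",
    "EXITED",
    "STUCK",
    "SimConfig",
    "SwarmState",
    "SeedSpec",
    "InvalidSeedError",
    "seed_particles",
    "semi_static_velocity",
    "resolve_collision",
    "minor_step",
    "major_step",
    "run_simulation",
]

ACTIVE, EXITED, STUCK = 0, 1, 2

_MAX_REFLECTIONS = 4
_BISECT_TOL = 1e-9  # m


@dataclass(frozen=True)
class SimConfig:
    """Integration, population and physics-coupling parameters.

    The loop-rate contract is dt_minor * minors_per_major == major_period
    (0.002 s * 25 == 0.05 s by default). ``drag_diameter_mode`` selects the
    Stokes diameter: the individual particle diameter d (default, literal
    Stokes law) or the chain equivalent diameter D_eq (sensitivity studies).
    """

    dt_minor: float = 0.05 / 25
    minors_per_major: int = 25
    major_period: float = 0.05
    n_particles: int = 500
    drag_diameter_mode: str = "particle_d"  # or "equivalent_Deq"
    wall_friction_mu: float = 0.0
    max_sim_time: float = 30.0
    rng_seed: int = 0
    gradient_limit_mT_m: float = 500.0
    viscosity: float = 1e-3

    def __post_init__(self) -> None:
        if abs(self.dt_minor * self.minors_per_major - self.major_period) > 1e-12:
            raise ValueError("dt_minor * minors_per_major must equal major_period")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.drag_diameter_mode not in ("particle_d", "equivalent_Deq"):
            raise ValueError("unknown drag_diameter_mode")
        if not 0.0 <= self.wall_friction_mu <= 1.0:
            raise ValueError("wall_friction_mu must lie in [0, 1]")

    def drag_diameter(self, params: MagneticParams) -> float:
        return params.d if self.drag_diameter_mode == "particle_d" else params.D_eq


@dataclass
class SwarmState:
    """Positions, velocities and lifecycle status of the N particles."""

    positions: np.ndarray  # (N, 2) m
    velocities: np.ndarray  # (N, 2) m/s
    status: np.ndarray  # (N,) int: ACTIVE / EXITED / STUCK
    exit_outlet: list  # (N,) outlet id or None
    exit_time: np.ndarray  # (N,) s, nan while active
    t: float = 0.0

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def active_mask(self) -> np.ndarray:
        return self.status == ACTIVE

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.status == ACTIVE))

    def copy(self) -> "SwarmState":
        return SwarmState(
            self.positions.copy(),
            self.velocities.copy(),
            self.status.copy(),
            list(self.exit_outlet),
            self.exit_time.copy(),
            self.t,
        )


class InvalidSeedError(ValueError):
    """Seeding square does not lie inside the lumen."""


@dataclass(frozen=True)
class SeedSpec:
    """Initial placement: one clump square, or split between two squares.

    The squares are axis-aligned (center, side). Defaults put the clump square
    (side 0.6 mm, comparable to the channel width) centered on the inlet
    segment 1 mm downstream of the inlet gate; the split mode adds a matching
    square 1 mm past the first junction.
    """

    mode: str = "clump"  # or "split"
    clump_center: tuple[float, float] = (1.0e-3, 0.0)
    clump_side: float = 0.6e-3
    second_center: tuple[float, float] = (6.0e-3, 0.0)
    second_side: float = 0.6e-3

    def __post_init__(self) -> None:
        if self.mode not in ("clump", "split"):
            raise ValueError("mode must be 'clump' or 'split'")
        if self.clump_side <= 0 or self.second_side <= 0:
            raise ValueError("square sides must be > 0")


def _square_corners(center, side):
    c = np.asarray(center, float)
    h = side / 2.0
    return c + np.array([[-h, -h], [-h, h], [h, -h], [h, h]])


def seed_particles(
    spec: SeedSpec, n: int, rng_seed: int, lumen: LumenPolygon | None = None
) -> SwarmState:
    """Place ``n`` particles uniformly i.i.d. in the seeding square(s)."""
    rng = np.random.default_rng(rng_seed)
    squares = [(spec.clump_center, spec.clump_side)]
    counts = [n]
    if spec.mode == "split":
        counts = [(n + 1) // 2, n // 2]
        squares.append((spec.second_center, spec.second_side))
    if lumen is not None:
        for center, side in squares:
            if not lumen.contains_batch(_square_corners(center, side)).all():
                raise InvalidSeedError(
                    f"seeding square at {tuple(center)} (side {side}) leaves the lumen"
                )
    parts = []
    for (center, side), k in zip(squares, counts):
        c = np.asarray(center, float)
        parts.append(c + (rng.random((k, 2)) - 0.5) * side)
    positions = np.vstack(parts)
    return SwarmState(
        positions=positions,
        velocities=np.zeros_like(positions),
        status=np.full(n, ACTIVE, dtype=np.int8),
        exit_outlet=[None] * n,
        exit_time=np.full(n, np.nan),
        t=0.0,
    )


def semi_static_velocity(F_applied, v_f, eta: float, d_drag: float) -> np.ndarray:
    """Particle velocity from the drag balance: v_p = v_f + F / (3 pi eta d)."""
    if eta <= 0 or d_drag <= 0:
        raise ValueError("eta and d_drag must be > 0")
    return np.asarray(v_f, float) + np.asarray(F_applied, float) / (3.0 * np.pi * eta * d_drag)


def _reflect_batch(vec: np.ndarray, normal: np.ndarray, mu: float) -> np.ndarray:
    """Reflect vectors about the wall tangent; attenuate tangential part by 1-mu."""
    vn = np.einsum("ij,ij->i", vec, normal)[:, None] * normal
    vt = vec - vn
    return (1.0 - mu) * vt - vn


def _resolve_collisions_batch(p0, p1, v, polygon: LumenPolygon, mu: float):
    """Resolve wall crossings for steps p0 (inside) -> p1 (outside).

    Returns corrected positions, velocities, and a stuck mask for corner traps.
    """
    p0 = np.array(p0, float)
    p1 = np.array(p1, float)
    v = np.array(v, float)
    k = len(p0)
    stuck = np.zeros(k, bool)
    todo = np.arange(k)
    for _attempt in range(_MAX_REFLECTIONS):
        if todo.size == 0:
            break
        a = p0[todo]
        b = p1[todo]
        d = b - a
        step = np.linalg.norm(d, axis=1)
        # bisect the crossing parameter so the bracket is below tolerance
        lo = np.zeros(len(todo))
        hi = np.ones(len(todo))
        max_step = float(step.max(initial=0.0))
        n_iter = max(1, int(np.ceil(np.log2(max(max_step, _BISECT_TOL) / _BISECT_TOL))) + 1)
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            ins = polygon.contains_batch(a + mid[:, None] * d)
            lo = np.where(ins, mid, lo)
            hi = np.where(ins, hi, mid)
        contact = a + lo[:, None] * d  # inside, within tol of the wall
        _, normal = polygon.nearest_boundary_batch(a + hi[:, None] * d)
        residual = (1.0 - lo)[:, None] * d
        p_new = contact + _reflect_batch(residual, normal, mu)
        v[todo] = _reflect_batch(v[todo], normal, mu)
        p0[todo] = contact
        p1[todo] = p_new
        ok = polygon.contains_batch(p_new)
        todo = todo[~ok]
    if todo.size:
        # corner trap: leave the particle at its last wall contact
        stuck[todo] = True
        p1[todo] = p0[todo]
        v[todo] = 0.0
    return p1, v, stuck


def resolve_collision(p_prev, p_proposed, v_p, polygon: LumenPolygon, mu: float = 0.0):
    """Single-particle collision resolution (see module docstring)."""
    p, v, stuck = _resolve_collisions_batch(
        np.asarray(p_prev, float)[None, :],
        np.asarray(p_proposed, float)[None, :],
        np.asarray(v_p, float)[None, :],
        polygon,
        mu,
    )
    return p[0], v[0], bool(stuck[0])


def minor_step(
    state: SwarmState,
    cmd: GradientCommand,
    flow,
    polygon: LumenPolygon,
    graph: NetworkGraph,
    config: SimConfig,
    params: MagneticParams,
) -> SwarmState:
    """Advance all active particles by one MiL timestep (in place)."""
    F = magnetic_force(params, cmd)
    return _minor_step_fast(
        state,
        F / (3.0 * np.pi * config.viscosity * config.drag_diameter(params)),
        flow,
        polygon,
        graph,
        config,
    )


def _minor_step_fast(state, drift, flow, polygon, graph, config) -> SwarmState:
    """Inner step with the magnetic drift velocity precomputed."""
    dt = config.dt_minor
    act = np.flatnonzero(state.status == ACTIVE)
    if act.size:
        p0 = state.positions[act]
        # active positions are inside the lumen by invariant
        v_p = flow.sample_batch(p0, assume_inside=True) + drift
        p1 = p0 + v_p * dt

        inside = polygon.contains_batch(p1)
        state.positions[act] = p1
        state.velocities[act] = v_p
        if not inside.all():
            # leaving the lumen: either through an outlet gate (exit) or a wall
            left = np.flatnonzero(~inside)
            gate = crossed_outlets(graph, p0[left], p1[left])
            exited = gate >= 0
            if exited.any():
                idx = act[left[exited]]
                state.status[idx] = EXITED
                state.exit_time[idx] = state.t + dt
                for i, g in zip(idx, gate[exited]):
                    state.exit_outlet[i] = graph.outlets[g].id
            hit_wall = left[~exited]
            if hit_wall.size:
                idx = act[hit_wall]
                pc, vc, stuck = _resolve_collisions_batch(
                    p0[hit_wall], p1[hit_wall], v_p[hit_wall], polygon,
                    config.wall_friction_mu,
                )
                state.positions[idx] = pc
                state.velocities[idx] = vc
                if stuck.any():
                    sidx = idx[stuck]
                    state.status[sidx] = STUCK
                    state.exit_time[sidx] = state.t + dt
    state.t += dt
    return state


def major_step(
    state: SwarmState,
    policy,
    flow,
    polygon: LumenPolygon,
    graph: NetworkGraph,
    config: SimConfig,
    params: MagneticParams,
) -> tuple[SwarmState, MajorRecord]:
    """One MaL iteration: query the policy once, run 25 minor steps, log."""
    raw = np.asarray(policy(state, graph, graph.goal_outlet, state.t), float)
    cmd = limit_gradient(raw, config.gradient_limit_mT_m)
    F = magnetic_force(params, cmd)
    drift = F / (3.0 * np.pi * config.viscosity * config.drag_diameter(params))
    major_index = round(state.t / config.major_period)
    for _ in range(config.minors_per_major):
        _minor_step_fast(state, drift, flow, polygon, graph, config)
    # snap the clock to the exact major-period multiple (no fp drift)
    state.t = (major_index + 1) * config.major_period
    record = MajorRecord(
        t=state.t, raw=raw.copy(), command=cmd.vector, positions=state.positions.copy()
    )
    return state, record


def _config_hash(config: SimConfig, params: MagneticParams) -> str:
    payload = json.dumps({"config": asdict(config), "params": asdict(params)}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_simulation(
    config: SimConfig,
    graph: NetworkGraph,
    flow,
    policy,
    seed_spec: SeedSpec,
    params: MagneticParams | None = None,
    polygon: LumenPolygon | None = None,
) -> RunLog:
    """Run major steps until every particle has exited/stuck or time runs out."""
    params = params if params is not None else MagneticParams()
    polygon = polygon if polygon is not None else network_to_polygon(graph)
    state = seed_particles(spec=seed_spec, n=config.n_particles, rng_seed=config.rng_seed, lumen=polygon)
    records: list[MajorRecord] = []
    while state.n_active > 0 and state.t < config.max_sim_time - 1e-12:
        state, record = major_step(state, policy, flow, polygon, graph, config, params)
        records.append(record)
    outcomes = pd.DataFrame(
        {
            "particle": np.arange(state.n),
            "status": [STATUS_NAMES[s] for s in state.status],
            "exit_outlet": state.exit_outlet,
            "exit_time": state.exit_time,
        }
    )
    metadata = {
        "seed": config.rng_seed,
        "config_hash": _config_hash(config, params),
        "policy": getattr(policy, "describe", lambda: repr(policy))(),
        "goal_outlet": graph.goal_outlet,
        "n_particles": state.n,
        "final_time": state.t,
    }
    return RunLog(records, outcomes, metadata)
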