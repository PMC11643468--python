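"""Steering policies: scripted stand-ins for the human operator.

A policy is a callable ``(state, graph, goal_outlet, t) -> raw`` returning the
dimensionless 2-vector the haptic device would supply (magnitude <= 1; larger
outputs are renormalized downstream by the gradient limiter). Three policies
are provided: a constant input, replay of a recorded log, and a waypoint
autopilot that emulates an experienced operator.

The autopilot plans waypoints along the unique inlet -> goal path, offsetting
each leg toward the goal-side wall (the side away from competing branch
mouths). Because the magnetic drift (about 1.8 mm/s at 1000 mT/m) is an order
of magnitude below the channel flows, steering authority is spent across the
channel rather than along it: the emitted input blends a saturated cross-track
correction toward the offset waypoint line with a small along-track cruise
term, and the flow provides the downstream transport — the strategy a human
operator converges on.

``haptic_workspace_mapping`` is the pure-function model of the device-side
input map: displacement over the ~10 cm workspace scales linearly to the unit
disc, with the restoring-spring force reported for interface completeness.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import NetworkGraph, _node_key
from .runlog import RunLog

__all__ = [
    "WaypointPlan",
    "ConstantPolicy",
    "ReplayPolicy",
    "WaypointAutopilot",
    "constant_policy",
    "replay_policy",
    "waypoint_autopilot",
    "haptic_workspace_mapping",
]


def _unit_clamp(v: np.ndarray) -> np.ndarray:
    mag = float(np.linalg.norm(v))
    return v / mag if mag > 1.0 else v


@dataclass
class WaypointPlan:
    """Ordered waypoints from the seeding region to beyond the goal gate."""

    waypoints: np.ndarray  # (k, 2) m
    capture_radius: float

    def __post_init__(self) -> None:
        w = np.asarray(self.waypoints, float)
        if len(w) < 2:
            raise ValueError("a plan needs at least two waypoints")
        if np.any(np.all(w[1:] == w[:-1], axis=1)):
            raise ValueError("consecutive waypoints must be distinct")
        self.waypoints = w

    @property
    def legs(self):
        return self.waypoints[:-1], self.waypoints[1:]


class ConstantPolicy:
    """Emit the same raw input at every query."""

    def __init__(self, raw):
        self.raw = _unit_clamp(np.asarray(raw, float))

    def __call__(self, state, graph, goal, t) -> np.ndarray:
        return self.raw.copy()

    def describe(self) -> str:
        return f"constant({self.raw[0]:g},{self.raw[1]:g})"


class ReplayPolicy:
    """Replay the recorded raw inputs of a log, major step by major step."""

    def __init__(self, log: RunLog, major_period: float = 0.05):
        self.log = log
        self.major_period = major_period
        self._warned = False

    def __call__(self, state, graph, goal, t) -> np.ndarray:
        index = round(t / self.major_period)
        raw = self.log.raw_input_at(index)
        if raw is None:
            if not self._warned:
                warnings.warn(
                    f"no recorded input for major step {index}; emitting zero input"
                )
                self._warned = True
            return np.zeros(2)
        return _unit_clamp(np.asarray(raw, float))

    def describe(self) -> str:
        return f"replay({len(self.log.records)} records)"


class PlanningError(ValueError):
    """Goal outlet unreachable or plan degenerate."""


def _leg_offset(graph: NetworkGraph, a, b, path_keys, frac: float) -> np.ndarray:
    """Offset for the leg a -> b: away from non-path branch mouths at its ends."""
    u = (b - a) / np.linalg.norm(b - a)
    n = np.array([-u[1], u[0]])
    width = None
    score = 0.0
    for node in (a, b):
        k = _node_key(node)
        for seg in graph.segments:
            ks, ke = _node_key(seg.start), _node_key(seg.end)
            if k not in (ks, ke):
                continue
            if width is None and {ks, ke} <= path_keys:
                width = seg.width
            if {ks, ke} <= path_keys:
                continue  # on-path segment, not a competing mouth
            away = np.asarray(seg.end if k == ks else seg.start, float) - np.asarray(
                node, float
            )
            score -= float(np.dot(away / np.linalg.norm(away), n))
    if width is None:
        width = graph.segments[0].width
    if score == 0.0:
        return np.zeros(2)
    return np.sign(score) * frac * (width / 2.0) * n


class WaypointAutopilot:
    """Deterministic waypoint-following stand-in for the experienced user.

    Parameters
    ----------
    capture_radius : m, advance to the next leg when the active-swarm centroid
        is this close to the current leg's end.
    gain : scales the emitted raw input (clamped to unit magnitude).
    wall_offset_frac : waypoint offset toward the goal-side wall as a fraction
        of the half-width (0.7 places the target line 0.35 mm off-center in a
        1 mm vessel).
    cruise_weight : relative weight of the along-track term; the cross-track
        correction has weight 1 when saturated.
    cross_scale : m, cross-track error at which the correction saturates.
    """

    def __init__(
        self,
        graph: NetworkGraph,
        goal: str | None = None,
        capture_radius: float = 5e-4,
        gain: float = 1.0,
        wall_offset_frac: float = 0.7,
        cruise_weight: float = 0.35,
        cross_scale: float = 1e-4,
    ):
        self.goal = goal if goal is not None else graph.goal_outlet
        self.capture_radius = capture_radius
        self.gain = gain
        self.cruise_weight = cruise_weight
        self.cross_scale = cross_scale
        self.plan = self._build_plan(graph, wall_offset_frac)

    def _build_plan(self, graph: NetworkGraph, frac: float) -> WaypointPlan:
        try:
            nodes = graph.path_nodes_to_outlet(self.goal)
        except Exception as exc:
            raise PlanningError(f"cannot plan a path to {self.goal!r}: {exc}") from exc
        path_keys = {_node_key(p) for p in nodes}
        waypoints = []
        for a, b in zip(nodes[:-1], nodes[1:]):
            off = _leg_offset(graph, a, b, path_keys, frac)
            for p in (a + off, b + off):
                if not waypoints or np.linalg.norm(p - waypoints[-1]) > 1e-12:
                    waypoints.append(p)
        # final waypoint beyond the goal gate, along the last leg direction
        gate = graph.outlet(self.goal)
        g = np.asarray(gate.gate, float)
        gate_width = float(np.linalg.norm(g[1] - g[0]))
        u = waypoints[-1] - waypoints[-2]
        u = u / np.linalg.norm(u)
        waypoints.append(waypoints[-1] + u * gate_width)
        return WaypointPlan(np.asarray(waypoints), self.capture_radius)

    def __call__(self, state, graph, goal, t) -> np.ndarray:
        from .dynamics import ACTIVE

        active = state.status == ACTIVE
        if not active.any():
            return np.zeros(2)
        c = state.positions[active].mean(axis=0)

        a, b = self.plan.legs
        d = b - a
        length = np.linalg.norm(d, axis=1)
        u = d / length[:, None]
        ap = c[None, :] - a
        s = np.clip(np.einsum("ij,ij->i", ap, u), 0.0, length)
        foot = a + s[:, None] * u
        dist = np.linalg.norm(c[None, :] - foot, axis=1)
        # active leg: nearest, preferring the later leg on ties
        j = len(dist) - 1 - int(np.argmin(dist[::-1]))
        # capture: hop to the next leg once the current leg end is reached
        while j < len(a) - 1 and np.linalg.norm(b[j] - c) < self.capture_radius:
            j += 1

        uj = u[j]
        line_foot = a[j] + float(np.dot(c - a[j], uj)) * uj
        cross_vec = line_foot - c
        cross_err = float(np.linalg.norm(cross_vec))
        direction = self.cruise_weight * uj
        if cross_err > 0.0:
            direction = direction + min(cross_err / self.cross_scale, 1.0) * (
                cross_vec / cross_err
            )
        mag = float(np.linalg.norm(direction))
        if mag == 0.0:
            return np.zeros(2)
        return _unit_clamp(self.gain * direction / mag)

    def describe(self) -> str:
        return (
            f"waypoint_autopilot(goal={self.goal}, gain={self.gain:g}, "
            f"capture_radius={self.capture_radius:g})"
        )


def constant_policy(raw) -> ConstantPolicy:
    return ConstantPolicy(raw)


def replay_policy(log: RunLog, major_period: float = 0.05) -> ReplayPolicy:
    return ReplayPolicy(log, major_period)


def waypoint_autopilot(
    graph: NetworkGraph, goal: str | None = None, capture_radius: float = 5e-4, gain: float = 1.0, **kwargs
) -> WaypointAutopilot:
    return WaypointAutopilot(graph, goal, capture_radius, gain, **kwargs)


_SPRING_MAX_N = 4.0
_WORKSPACE_HALFWIDTH = 0.05  # m


def haptic_workspace_mapping(displacement, workspace_halfwidth: float = _WORKSPACE_HALFWIDTH):
    """Map a device displacement (m) to raw input; report the spring force.

    The raw input is displacement / halfwidth clamped to the unit disc. The
    device's restoring spring (maximum pull ~4 N at full deflection of the
    10 cm x 10 cm workspace) is returned as an advisory force vector directed
    back toward the rest position; it plays no role in the simulation.
    """
    if workspace_halfwidth <= 0:
        raise ValueError("workspace_halfwidth must be > 0")
    disp = np.asarray(displacement, float)
    raw = _unit_clamp(disp / workspace_halfwidth)
    k = _SPRING_MAX_N / workspace_halfwidth
    spring = -k * disp
    mag = float(np.linalg.norm(spring))
    if mag > _SPRING_MAX_N:
        spring = spring * (_SPRING_MAX_N / mag)
    return raw, spring
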