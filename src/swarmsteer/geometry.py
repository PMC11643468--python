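"""Vessel-network geometry for the steering simulator.

The navigable domain is a planar channel network: straight vessel segments of
constant width whose union forms the lumen polygon. The default fixture is a
"comb" network — one horizontal main channel fed by a single inlet, with a
downward branch leaving at each of four junctions, giving one inlet and five
outlets. Containment tests against the lumen polygon drive collision handling,
and directed outlet "gates" (the open end edge of each terminal vessel) decide
when a particle has left the network and through which outlet.

Coordinates are SI meters; the origin sits at the inlet-gate center, +x points
downstream along the main channel and +y up.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.geometry.polygon import orient
from shapely.ops import unary_union

__all__ = [
    "InvalidGeometryError",
    "VesselSegment",
    "Outlet",
    "NetworkGraph",
    "LumenPolygon",
    "build_comb_network",
    "network_to_polygon",
    "point_in_lumen",
    "nearest_boundary",
    "outlet_crossed",
    "crossed_outlets",
    "save_network_json",
    "load_network_json",
]

_NODE_DECIMALS = 9  # node-merging resolution, 1 nm


class InvalidGeometryError(ValueError):
    """Raised for degenerate or self-intersecting network geometry."""


@dataclass(frozen=True)
class VesselSegment:
    """A straight vessel of constant width, described by its centerline."""

    id: str
    start: tuple[float, float]
    end: tuple[float, float]
    width: float
    role: str = "main"  # one of {inlet, main, branch}

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InvalidGeometryError(f"segment {self.id}: width must be > 0")
        if self.length == 0:
            raise InvalidGeometryError(f"segment {self.id}: start == end")

    @property
    def length(self) -> float:
        return math.dist(self.start, self.end)

    @property
    def axis(self) -> np.ndarray:
        """Unit vector along the centerline, start -> end."""
        d = np.asarray(self.end, float) - np.asarray(self.start, float)
        return d / np.linalg.norm(d)

    @property
    def normal(self) -> np.ndarray:
        """Unit normal (axis rotated +90 deg)."""
        u = self.axis
        return np.array([-u[1], u[0]])

    def local_frame(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Along/cross coordinates of ``points`` (..., 2) in the segment frame."""
        p = np.asarray(points, float) - np.asarray(self.start, float)
        return p @ self.axis, p @ self.normal

    def contains(self, points: np.ndarray, tol: float = 1e-12) -> np.ndarray:
        """Vectorized membership in the segment rectangle (boundary inclusive)."""
        along, cross = self.local_frame(points)
        return (
            (along >= -tol)
            & (along <= self.length + tol)
            & (np.abs(cross) <= self.width / 2 + tol)
        )

    def rectangle(self) -> ShapelyPolygon:
        a = np.asarray(self.start, float)
        b = np.asarray(self.end, float)
        n = self.normal * (self.width / 2)
        return ShapelyPolygon([a + n, b + n, b - n, a - n])


@dataclass(frozen=True)
class Outlet:
    """An exit gate: the directed open end edge of a terminal vessel."""

    id: str
    gate: tuple[tuple[float, float], tuple[float, float]]

    @property
    def center(self) -> np.ndarray:
        g = np.asarray(self.gate, float)
        return g.mean(axis=0)


def _node_key(p) -> tuple[float, float]:
    return (round(float(p[0]), _NODE_DECIMALS), round(float(p[1]), _NODE_DECIMALS))


@dataclass
class NetworkGraph:
    """A channel network: segments plus inlet, junctions and outlet gates."""

    segments: list[VesselSegment]
    inlet_node: tuple[float, float]
    outlets: list[Outlet]
    goal_outlet: str
    junctions: list[tuple[tuple[float, float], list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.junctions:
            self.junctions = self._find_junctions()
        if self.goal_outlet not in {o.id for o in self.outlets}:
            raise InvalidGeometryError(f"goal outlet {self.goal_outlet!r} not in outlets")

    def _adjacency(self) -> dict[tuple[float, float], list[VesselSegment]]:
        adj: dict[tuple[float, float], list[VesselSegment]] = {}
        for seg in self.segments:
            for p in (seg.start, seg.end):
                adj.setdefault(_node_key(p), []).append(seg)
        return adj

    def _find_junctions(self):
        return [
            (node, [s.id for s in segs])
            for node, segs in self._adjacency().items()
            if len(segs) >= 3
        ]

    def segment(self, seg_id: str) -> VesselSegment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise KeyError(seg_id)

    def outlet(self, outlet_id: str) -> Outlet:
        for o in self.outlets:
            if o.id == outlet_id:
                return o
        raise KeyError(outlet_id)

    def path_nodes_to_outlet(self, outlet_id: str) -> list[np.ndarray]:
        """Node coordinates along the (unique, BFS-shortest) inlet -> outlet path.

        The final node is the outlet gate center (the open end of the terminal
        vessel).
        """
        adj = self._adjacency()
        target = _node_key(self.outlet(outlet_id).center)
        start = _node_key(self.inlet_node)
        prev: dict[tuple[float, float], tuple[float, float] | None] = {start: None}
        queue = [start]
        while queue:
            node = queue.pop(0)
            if node == target:
                break
            for seg in adj[node]:
                for p in (seg.start, seg.end):
                    k = _node_key(p)
                    if k not in prev:
                        prev[k] = node
                        queue.append(k)
        if target not in prev:
            raise InvalidGeometryError(f"outlet {outlet_id!r} unreachable from inlet")
        path = []
        node: tuple[float, float] | None = target
        while node is not None:
            path.append(np.asarray(node, float))
            node = prev[node]
        return path[::-1]

    def path_segments_to_outlet(self, outlet_id: str) -> list[VesselSegment]:
        """Segments traversed on the inlet -> outlet path, in order."""
        nodes = self.path_nodes_to_outlet(outlet_id)
        adj = self._adjacency()
        segs = []
        for a, b in zip(nodes[:-1], nodes[1:]):
            ka, kb = _node_key(a), _node_key(b)
            for seg in adj[ka]:
                if {_node_key(seg.start), _node_key(seg.end)} == {ka, kb}:
                    segs.append(seg)
                    break
            else:  # pragma: no cover - defensive
                raise InvalidGeometryError("path reconstruction failed")
        return segs


class LumenPolygon:
    """The navigable region: union of segment rectangles with junctions filled.

    Containment uses the per-segment rectangle test (a point lies in the union
    iff it lies in some rectangle), which is exact, boundary-inclusive and
    vectorizes over particle arrays; the shapely polygon backs area, boundary
    extraction and nearest-boundary queries.
    """

    def __init__(self, polygon: ShapelyPolygon, segments: list[VesselSegment] | None = None):
        if not polygon.is_valid or polygon.is_empty:
            raise InvalidGeometryError("lumen polygon is invalid or empty")
        self.polygon = orient(polygon, sign=1.0)  # exterior CCW, holes CW
        self.segments = list(segments) if segments else None
        self._edges = self._build_edges()
        self._prepared = shapely.prepared.prep(self.polygon)
        if self.segments:
            # precomputed segment frames for the vectorized containment test
            self._seg_origin = np.array([s.start for s in self.segments], float)
            self._seg_axis = np.array([s.axis for s in self.segments])
            self._seg_normal = np.array([s.normal for s in self.segments])
            self._seg_len = np.array([s.length for s in self.segments])
            self._seg_halfw = np.array([s.width / 2 for s in self.segments])

    # -- construction helpers -------------------------------------------------
    def _build_edges(self):
        rings = [np.asarray(self.polygon.exterior.coords)]
        rings += [np.asarray(r.coords) for r in self.polygon.interiors]
        a = np.vstack([r[:-1] for r in rings])
        b = np.vstack([r[1:] for r in rings])
        d = b - a
        length = np.linalg.norm(d, axis=1)
        keep = length > 0
        a, b, d, length = a[keep], b[keep], d[keep], length[keep]
        u = d / length[:, None]
        # with exterior CCW / holes CW the interior lies to the left of every
        # directed edge, so the inward normal is the +90 deg rotation
        inward = np.stack([-u[:, 1], u[:, 0]], axis=1)
        return a, b, u, length, inward

    # -- queries --------------------------------------------------------------
    @property
    def boundary(self) -> np.ndarray:
        """Exterior ring vertices, (k, 2), closed (first == last)."""
        return np.asarray(self.polygon.exterior.coords)

    @property
    def holes(self) -> list[np.ndarray]:
        return [np.asarray(r.coords) for r in self.polygon.interiors]

    @property
    def area(self) -> float:
        return self.polygon.area

    def contains_batch(self, points: np.ndarray, tol: float = 1e-12) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        if self.segments is not None:
            rel = points[:, None, :] - self._seg_origin[None, :, :]  # (P, S, 2)
            along = np.einsum("psj,sj->ps", rel, self._seg_axis)
            cross = np.einsum("psj,sj->ps", rel, self._seg_normal)
            ok = (
                (along >= -tol)
                & (along <= self._seg_len[None, :] + tol)
                & (np.abs(cross) <= self._seg_halfw[None, :] + tol)
            )
            return ok.any(axis=1)
        return shapely.covers(self.polygon, shapely.points(points))

    def contains(self, p, tol: float = 1e-12) -> bool:
        return bool(self.contains_batch(np.asarray(p, float)[None, :], tol=tol)[0])

    def nearest_boundary_batch(self, points: np.ndarray):
        """Closest boundary foot and inward unit normal for each point.

        Ties between edges (corners) are broken by edge order; any tied foot is
        an acceptable answer.
        """
        points = np.atleast_2d(np.asarray(points, float))
        a, b, u, length, inward = self._edges
        ap = points[:, None, :] - a[None, :, :]  # (P, E, 2)
        t = np.clip(np.einsum("pej,ej->pe", ap, u) / length[None, :], 0.0, 1.0)
        foot = a[None, :, :] + t[:, :, None] * (b - a)[None, :, :]
        d2 = np.sum((points[:, None, :] - foot) ** 2, axis=2)
        j = np.argmin(d2, axis=1)
        rows = np.arange(len(points))
        return foot[rows, j], inward[j]

    def nearest_boundary(self, p) -> tuple[np.ndarray, np.ndarray]:
        foot, normal = self.nearest_boundary_batch(np.asarray(p, float)[None, :])
        return foot[0], normal[0]


def build_comb_network(
    n_branches: int = 4,
    width: float = 1e-3,
    seg_length: float = 5e-3,
    branch_angle: float = math.pi / 2,
    goal_outlet: str | None = None,
) -> NetworkGraph:
    """Build the one-inlet comb network: a straight main channel with a branch
    leaving at each junction.

    The main channel runs along +x as ``n_branches + 1`` collinear segments of
    ``seg_length``; at each internal junction one branch of the same width and
    length leaves at ``branch_angle`` measured clockwise from +x (pi/2 gives a
    straight-down branch). Outlet count is ``n_branches + 1``: the open end of
    each branch plus the far end of the main channel. The default goal outlet
    is the main-channel end.
    """
    if n_branches < 1:
        raise InvalidGeometryError("n_branches must be >= 1")
    if width <= 0 or seg_length <= 0:
        raise InvalidGeometryError("width and seg_length must be > 0")

    segments: list[VesselSegment] = []
    outlets: list[Outlet] = []
    branch_dir = np.array([math.cos(-branch_angle), math.sin(-branch_angle)])
    half_w = width / 2

    for i in range(n_branches + 1):
        x0, x1 = i * seg_length, (i + 1) * seg_length
        role = "inlet" if i == 0 else "main"
        segments.append(VesselSegment(f"main{i}", (x0, 0.0), (x1, 0.0), width, role))

    for j in range(1, n_branches + 1):
        node = np.array([j * seg_length, 0.0])
        end = node + branch_dir * seg_length
        segments.append(
            VesselSegment(f"branch{j}", tuple(node), tuple(end), width, "branch")
        )
        # gate: end edge of the branch, perpendicular to its axis
        n = np.array([-branch_dir[1], branch_dir[0]]) * half_w
        outlets.append(Outlet(f"out_branch{j}", (tuple(end + n), tuple(end - n))))

    x_end = (n_branches + 1) * seg_length
    outlets.append(
        Outlet("out_main", ((x_end, half_w), (x_end, -half_w)))
    )
    goal = goal_outlet if goal_outlet is not None else "out_main"
    return NetworkGraph(segments, (0.0, 0.0), outlets, goal)


def network_to_polygon(graph: NetworkGraph) -> LumenPolygon:
    """Union of per-segment rectangles (centerline +- width/2), junctions filled."""
    merged = unary_union([s.rectangle() for s in graph.segments])
    if merged.geom_type != "Polygon":
        raise InvalidGeometryError(
            f"segment rectangles do not form a single simple polygon ({merged.geom_type})"
        )
    return LumenPolygon(merged, graph.segments)


def point_in_lumen(polygon: LumenPolygon, p) -> bool:
    """True iff ``p`` is inside or on the boundary of the lumen."""
    return polygon.contains(p)


def nearest_boundary(polygon: LumenPolygon, p) -> tuple[np.ndarray, np.ndarray]:
    """Closest boundary point to ``p`` and the inward unit normal there."""
    return polygon.nearest_boundary(p)


def _cross2(o, a, b):
    return (a[..., 0] - o[..., 0]) * (b[..., 1] - o[..., 1]) - (
        a[..., 1] - o[..., 1]
    ) * (b[..., 0] - o[..., 0])


def _gate_arrays(graph: NetworkGraph):
    cached = getattr(graph, "_gate_cache", None)
    if cached is None:
        a = np.array([o.gate[0] for o in graph.outlets], float)  # (G, 2)
        b = np.array([o.gate[1] for o in graph.outlets], float)
        cached = (a, b)
        graph._gate_cache = cached
    return cached


def crossed_outlets(graph: NetworkGraph, p_prev: np.ndarray, p_new: np.ndarray) -> np.ndarray:
    """Index (into graph.outlets) of the gate each step crosses, -1 if none.

    Vectorized over particle steps and gates; endpoint touches count as
    crossings; zero-length steps never cross. The first matching gate (in
    outlet order) wins.
    """
    p_prev = np.atleast_2d(np.asarray(p_prev, float))
    p_new = np.atleast_2d(np.asarray(p_new, float))
    a, b = _gate_arrays(graph)  # (G, 2) each
    pp = p_prev[:, None, :]  # (P, 1, 2)
    pn = p_new[:, None, :]
    d1 = _cross2(pp, pn, a[None, :, :])
    d2 = _cross2(pp, pn, b[None, :, :])
    d3 = _cross2(a[None, :, :], b[None, :, :], pp)
    d4 = _cross2(a[None, :, :], b[None, :, :], pn)
    crossing = (d1 * d2 <= 0) & (d3 * d4 <= 0)  # (P, G)
    moving = np.any(p_prev != p_new, axis=1)
    crossing &= moving[:, None]
    hit = np.where(crossing.any(axis=1), np.argmax(crossing, axis=1), -1)
    return hit


def outlet_crossed(graph: NetworkGraph, p_prev, p_new) -> str | None:
    """Outlet id whose gate the directed step p_prev -> p_new crosses, else None."""
    idx = crossed_outlets(graph, np.asarray(p_prev, float)[None, :], np.asarray(p_new, float)[None, :])[0]
    return graph.outlets[idx].id if idx >= 0 else None


# -- JSON interchange ---------------------------------------------------------

_NETWORK_SCHEMA = "swarmsteer.network/1"


def save_network_json(graph: NetworkGraph, path) -> None:
    doc = {
        "schema": _NETWORK_SCHEMA,
        "segments": [
            {
                "id": s.id,
                "start": list(s.start),
                "end": list(s.end),
                "width": s.width,
                "role": s.role,
            }
            for s in graph.segments
        ],
        "inlet_node": list(graph.inlet_node),
        "outlets": [
            {"id": o.id, "gate": [list(o.gate[0]), list(o.gate[1])]} for o in graph.outlets
        ],
        "goal_outlet": graph.goal_outlet,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_network_json(path) -> NetworkGraph:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != _NETWORK_SCHEMA:
        raise InvalidGeometryError(
            f"unsupported network schema {doc.get('schema')!r}, expected {_NETWORK_SCHEMA!r}"
        )
    segments = [
        VesselSegment(
            d["id"], tuple(d["start"]), tuple(d["end"]), d["width"], d.get("role", "main")
        )
        for d in doc["segments"]
    ]
    outlets = [Outlet(d["id"], (tuple(d["gate"][0]), tuple(d["gate"][1]))) for d in doc["outlets"]]
    return NetworkGraph(segments, tuple(doc["inlet_node"]), outlets, doc["goal_outlet"])
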