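"""Poiseuille flow in the channel network and the runtime lookup table.

The fluid model is an analytic stand-in for a finite-element solve: each
segment is a 2D slit of width w carrying fully developed plane Poiseuille flow,
so its hydraulic conductance per unit depth is w^3 / (12 eta L) and the
transverse velocity profile is parabolic, v(s) = v_c (1 - (2s/w)^2) with
centerline velocity v_c = (3/2) Q / w. Node pressures solve the linear mass
conservation system with all outlets held at a common reference pressure and a
prescribed inlet inflow Q_in = (2/3) v_c,inlet w.

At run time velocities come from a lookup table sampled on a rectangular grid
over the lumen (~7000 points for the default network at the default spacing),
queried by nearest neighbor; points outside the lumen sample as zero velocity.
A CSV interchange path allows substituting an externally computed field.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import LumenPolygon, NetworkGraph, VesselSegment, network_to_polygon, _node_key

__all__ = [
    "FlowFieldConfig",
    "HydraulicSolution",
    "FlowLookupTable",
    "ConstantFlow",
    "FlowCSVError",
    "solve_network_flow",
    "local_velocity",
    "build_lookup_table",
    "sample_flow",
    "write_flow_csv",
    "read_flow_csv",
    "DEFAULT_SPACING",
]

#: grid spacing (m) giving >= 7000 in-lumen points on the default comb network
DEFAULT_SPACING = 7.5e-5


class FlowCSVError(ValueError):
    """Malformed flow-table CSV."""


@dataclass(frozen=True)
class FlowFieldConfig:
    """Fluid model parameters.

    inlet_central_velocity: centerline velocity at the inlet, m/s (the studied
        range is 0.005-0.06 m/s, capillary-like).
    viscosity: dynamic viscosity, Pa s (water: 1e-3).
    """

    inlet_central_velocity: float = 0.005
    viscosity: float = 1e-3
    fluid: str = "water"

    def __post_init__(self) -> None:
        if self.inlet_central_velocity <= 0:
            raise ValueError("inlet_central_velocity must be > 0")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0")


@dataclass
class HydraulicSolution:
    """Per-segment flows/centerline velocities and node pressures.

    flows[seg_id] is the volumetric flow per unit depth Q (m^2/s), signed along
    the segment's start -> end direction; central_velocity[seg_id] = 1.5 Q / w.
    Pressures are in arbitrary units (per-unit-depth, reference at outlets).
    """

    flows: dict[str, float]
    central_velocity: dict[str, float]
    pressures: dict[tuple[float, float], float]
    inlet_flow: float


def solve_network_flow(graph: NetworkGraph, config: FlowFieldConfig) -> HydraulicSolution:
    """Solve the hydraulic (resistor-network) problem on the channel graph."""
    nodes: list[tuple[float, float]] = []
    index: dict[tuple[float, float], int] = {}

    def node_id(p) -> int:
        k = _node_key(p)
        if k not in index:
            index[k] = len(nodes)
            nodes.append(k)
        return index[k]

    ends = []
    conduct = []
    for seg in graph.segments:
        i, j = node_id(seg.start), node_id(seg.end)
        ends.append((i, j))
        conduct.append(seg.width**3 / (12.0 * config.viscosity * seg.length))

    n = len(nodes)
    inlet = node_id(graph.inlet_node)
    outlet_nodes = {node_id(o.center) for o in graph.outlets}

    inlet_seg = next(
        s
        for s in graph.segments
        if _node_key(graph.inlet_node) in (_node_key(s.start), _node_key(s.end))
    )
    q_in = (2.0 / 3.0) * config.inlet_central_velocity * inlet_seg.width

    # nodal analysis: G p = q, outlets grounded at p = 0
    G = np.zeros((n, n))
    rhs = np.zeros(n)
    for (i, j), g in zip(ends, conduct):
        G[i, i] += g
        G[j, j] += g
        G[i, j] -= g
        G[j, i] -= g
    rhs[inlet] = q_in
    free = np.array([k for k in range(n) if k not in outlet_nodes], dtype=int)
    if free.size:
        try:
            p_free = np.linalg.solve(G[np.ix_(free, free)], rhs[free])
        except np.linalg.LinAlgError as exc:
            raise ValueError("hydraulic system is singular (disconnected graph?)") from exc
        pressures = np.zeros(n)
        pressures[free] = p_free
    else:
        pressures = np.zeros(n)

    flows = {}
    v_c = {}
    for seg, (i, j), g in zip(graph.segments, ends, conduct):
        q = g * (pressures[i] - pressures[j])
        flows[seg.id] = q
        v_c[seg.id] = 1.5 * q / seg.width
    return HydraulicSolution(
        flows, v_c, {nodes[k]: pressures[k] for k in range(n)}, q_in
    )


def local_velocity(solution: HydraulicSolution, segment: VesselSegment, p) -> np.ndarray:
    """Parabolic-profile velocity at ``p`` inside the segment rectangle."""
    p = np.asarray(p, float)
    if not segment.contains(p[None, :])[0]:
        raise ValueError(f"point {p} lies outside segment {segment.id}")
    _, s = segment.local_frame(p[None, :])
    vc = solution.central_velocity[segment.id]
    mag = vc * (1.0 - (2.0 * s[0] / segment.width) ** 2)
    return mag * segment.axis


@dataclass
class FlowLookupTable:
    """Point -> velocity samples with nearest-neighbor lookup.

    ``lumen`` (when present) decides the outside-is-zero convention exactly;
    for tables loaded from CSV without geometry, points farther than one
    nominal spacing from every sample are treated as outside.
    """

    points: np.ndarray  # (M, 2) m
    velocities: np.ndarray  # (M, 2) m/s
    spacing: float
    lumen: LumenPolygon | None = None
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)
    # exact-nearest grid accelerator (set when built on a regular grid):
    # grid node (i, j) -> row index of that table point, or -1 if absent
    _grid_index: np.ndarray | None = field(default=None, repr=False, compare=False)
    _grid_origin: tuple[float, float] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float).reshape(-1, 2)
        self.velocities = np.asarray(self.velocities, float).reshape(-1, 2)
        if len(self.points) != len(self.velocities):
            raise ValueError("points and velocities must have equal length")

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            if len(self.points) == 0:
                raise RuntimeError("empty flow lookup table")
            self._tree = cKDTree(self.points)
        return self._tree

    def _nearest_index(self, points: np.ndarray) -> np.ndarray:
        """Exact nearest-table-point row for each query point.

        On a regular grid the Euclidean-nearest grid node is the axis-wise
        rounded one; when that node carries a table point it is the exact
        nearest neighbor, so the O(1) grid lookup answers most queries and the
        KD-tree only resolves points whose rounded node was culled (near
        walls) or that fall outside the grid extent.
        """
        if self._grid_index is None:
            _, idx = self.tree.query(points)
            return idx
        x0, y0 = self._grid_origin
        nx, ny = self._grid_index.shape
        i = np.rint((points[:, 0] - x0) / self.spacing).astype(np.intp)
        j = np.rint((points[:, 1] - y0) / self.spacing).astype(np.intp)
        ok = (i >= 0) & (i < nx) & (j >= 0) & (j < ny)
        idx = np.full(len(points), -1, dtype=np.intp)
        idx[ok] = self._grid_index[i[ok], j[ok]]
        miss = idx < 0
        if miss.any():
            _, idx_miss = self.tree.query(points[miss])
            idx[miss] = idx_miss
        return idx

    def sample_batch(self, points: np.ndarray, assume_inside: bool = False) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        idx = self._nearest_index(points)
        v = self.velocities[idx].copy()
        if not assume_inside:
            if self.lumen is not None:
                outside = ~self.lumen.contains_batch(points)
            else:
                d = np.linalg.norm(points - self.points[idx], axis=1)
                outside = d > self.spacing
            v[outside] = 0.0
        return v

    def sample(self, p) -> np.ndarray:
        return self.sample_batch(np.asarray(p, float)[None, :])[0]


class ConstantFlow:
    """Uniform flow field (testing and open-workspace scenarios)."""

    def __init__(self, velocity=(0.0, 0.0)):
        self.velocity = np.asarray(velocity, float)

    def sample_batch(self, points: np.ndarray, assume_inside: bool = False) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        return np.broadcast_to(self.velocity, (len(points), 2)).copy()

    def sample(self, p) -> np.ndarray:
        return self.velocity.copy()


def build_lookup_table(
    graph: NetworkGraph,
    solution: HydraulicSolution,
    spacing: float = DEFAULT_SPACING,
    lumen: LumenPolygon | None = None,
) -> FlowLookupTable:
    """Sample the analytic field on a rectangular grid over the lumen.

    Grid nodes are kept when they lie in the lumen (boundary inclusive). A
    point covered by several segment rectangles (a junction) takes the velocity
    of the segment whose centerline is nearest.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if lumen is None:
        lumen = network_to_polygon(graph)
    xmin, ymin, xmax, ymax = lumen.polygon.bounds
    xs = np.arange(0, int(np.floor((xmax - xmin) / spacing + 1e-9)) + 1) * spacing + xmin
    ys = np.arange(0, int(np.floor((ymax - ymin) / spacing + 1e-9)) + 1) * spacing + ymin
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])

    n_seg = len(graph.segments)
    inside = np.zeros((len(pts), n_seg), bool)
    dist_cl = np.full((len(pts), n_seg), np.inf)
    vel = np.zeros((len(pts), n_seg, 2))
    for k, seg in enumerate(graph.segments):
        along, cross = seg.local_frame(pts)
        inside[:, k] = seg.contains(pts)
        # distance to the centerline segment (clamped to its extent)
        t = np.clip(along, 0.0, seg.length)
        dist_cl[:, k] = np.hypot(along - t, cross)
        mag = solution.central_velocity[seg.id] * (1.0 - (2.0 * cross / seg.width) ** 2)
        vel[:, k, :] = mag[:, None] * seg.axis
    dist_cl[~inside] = np.inf
    any_inside = inside.any(axis=1)
    owner = np.argmin(dist_cl[any_inside], axis=1)
    kept = pts[any_inside]
    v = vel[any_inside, owner, :]
    grid_index = np.full(len(pts), -1, dtype=np.intp)
    grid_index[any_inside] = np.arange(int(any_inside.sum()))
    table = FlowLookupTable(kept, v, spacing, lumen)
    table._grid_index = grid_index.reshape(len(xs), len(ys))
    table._grid_origin = (float(xs[0]), float(ys[0]))
    return table


def sample_flow(table: FlowLookupTable, p) -> np.ndarray:
    """Velocity of the nearest table point; zero outside the lumen."""
    return table.sample(p)


_CSV_COLUMNS = ["x_m", "y_m", "u_m_per_s", "v_m_per_s"]


def write_flow_csv(table: FlowLookupTable, path) -> None:
    df = pd.DataFrame(
        np.column_stack([table.points, table.velocities]), columns=_CSV_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_flow_csv(path, spacing: float | None = None, lumen: LumenPolygon | None = None) -> FlowLookupTable:
    """Read a flow table CSV (COMSOL-export style: extra columns are ignored).

    When ``spacing`` is not given it is estimated as the median nearest-
    neighbor distance between sample points.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FlowCSVError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FlowCSVError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in _CSV_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring extra columns {extra}", stacklevel=2)
    values = {}
    for c in _CSV_COLUMNS:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.index[col.isna() & df[c].notna()]
        if len(bad) or col.isna().any():
            row = int((bad[0] if len(bad) else col.index[col.isna()][0]))
            # +2: one for the header row, one for 1-based numbering
            raise FlowCSVError(f"{path}: non-numeric value in column {c!r} at line {row + 2}")
        values[c] = col.to_numpy(float)
    points = np.column_stack([values["x_m"], values["y_m"]])
    vels = np.column_stack([values["u_m_per_s"], values["v_m_per_s"]])
    if spacing is None:
        if len(points) >= 2:
            d, _ = cKDTree(points).query(points, k=2)
            spacing = float(np.median(d[:, 1]))
        else:
            spacing = np.inf
    return FlowLookupTable(points, vels, spacing, lumen)
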