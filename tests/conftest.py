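import numpy as np
import pytest

from swarmsteer.flowfield import FlowFieldConfig, build_lookup_table, solve_network_flow
from swarmsteer.geometry import (
    NetworkGraph,
    Outlet,
    VesselSegment,
    build_comb_network,
    network_to_polygon,
)


@pytest.fixture(scope="session")
def comb_graph():
    return build_comb_network()


@pytest.fixture(scope="session")
def comb_polygon(comb_graph):
    return network_to_polygon(comb_graph)


@pytest.fixture(scope="session")
def comb_flow(comb_graph, comb_polygon):
    solution = solve_network_flow(comb_graph, FlowFieldConfig(inlet_central_velocity=0.02))
    return build_lookup_table(comb_graph, solution, lumen=comb_polygon)


@pytest.fixture(scope="session")
def straight_graph():
    """A single 5 mm x 1 mm channel with its open end as the only outlet."""
    seg = VesselSegment("ch", (0.0, 0.0), (5e-3, 0.0), 1e-3, "inlet")
    outlet = Outlet("out", ((5e-3, 0.5e-3), (5e-3, -0.5e-3)))
    return NetworkGraph([seg], (0.0, 0.0), [outlet], "out")


@pytest.fixture(scope="session")
def straight_polygon(straight_graph):
    return network_to_polygon(straight_graph)


def ray_casting_inside(polygon_coords, holes, p):
    """Independent even-odd crossing-number point-in-polygon oracle."""

    def in_ring(ring, x, y):
        inside = False
        n = len(ring) - 1
        for i in range(n):
            x1, y1 = ring[i]
            x2, y2 = ring[i + 1]
            if (y1 > y) != (y2 > y):
                xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                if x < xi:
                    inside = not inside
        return inside

    x, y = p
    if not in_ring(polygon_coords, x, y):
        return False
    return not any(in_ring(h, x, y) for h in holes)
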