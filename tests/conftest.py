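import numpy as np
import pandas as pd
import pytest

from emsopt.road_network import RoadNetwork, SpeedModel
from emsopt.simulator import Hospital, SimulationConfig, Station
from emsopt.synthetic_data import generate_country, tiny_config


def make_network(nodes, edges, directed=False):
    """nodes: (id, x, y, built_up); edges: (a, b, length_km, category)."""
    nd = pd.DataFrame(nodes, columns=["node_id", "x_km", "y_km", "built_up"])
    ed = pd.DataFrame(edges, columns=["a", "b", "length_km", "category"])
    return RoadNetwork.from_frames(nd, ed, directed=directed)


def random_network(rng, n_nodes=15, extra_edges=8, built_up_frac=0.3):
    """Connected random graph: a random spanning tree plus chords."""
    xs = rng.uniform(0, 30, n_nodes)
    ys = rng.uniform(0, 30, n_nodes)
    built = rng.random(n_nodes) < built_up_frac
    nodes = [(i, xs[i], ys[i], bool(built[i])) for i in range(n_nodes)]
    cats = ["highway", "main", "local"]
    edges = []
    seen = set()
    order = rng.permutation(n_nodes)
    for k in range(1, n_nodes):
        a, b = int(order[k]), int(order[rng.integers(0, k)])
        seen.add((min(a, b), max(a, b)))
    for _ in range(extra_edges):
        a, b = rng.integers(0, n_nodes, 2)
        if a != b:
            seen.add((min(int(a), int(b)), max(int(a), int(b))))
    for a, b in sorted(seen):
        length = float(np.hypot(xs[a] - xs[b], ys[a] - ys[b])) + 0.1
        edges.append((a, b, length, cats[int(rng.integers(0, 3))]))
    return make_network(nodes, edges)


@pytest.fixture(scope="session")
def tiny_country():
    return generate_country(tiny_config(0))


@pytest.fixture
def line_world():
    """Three nodes on a line: station at 0, scene at 1, hospital at 2.

    Edge 0-1 is 7 km and 1-2 is 10 km of open main road, so at 60 km/h the
    legs take exactly 7 and 10 minutes for priority K off-peak.
    """
    network = make_network(
        nodes=[(0, 0.0, 0.0, False), (1, 7.0, 0.0, False), (2, 17.0, 0.0, False)],
        edges=[(0, 1, 7.0, "main"), (1, 2, 10.0, "main")],
    )
    stations = [Station(id="S0", node=0, kind="BLS", municipality="M0")]
    hospitals = [Hospital(id="H0", node=2, admits="both", dropoff_mean_min=15.0)]
    return network, stations, hospitals


@pytest.fixture
def static_speeds():
    """Speed model without time dependence (rush equals off-peak)."""
    return SpeedModel(
        base={"highway": (90.0, 90.0), "main": (60.0, 60.0), "local": (40.0, 40.0)}
    )


def call_stream(rows):
    """rows: (time_min, zone_id, node, priority, diagnosis, age_class)."""
    return pd.DataFrame(
        rows, columns=["time_min", "zone_id", "node", "priority", "diagnosis", "age_class"]
    )


def deterministic_sim_config(**kw):
    """Config with degenerate service distributions for hand-traced runs."""
    defaults = dict(
        horizon_days=2.0,
        n_replications=1,
        p_support=0.0,
        transport_prob={"BLS": 0.0, "ALS": 0.0},
        on_scene_default={"BLS": 20.0, "ALS": 20.0},
        on_scene_cv=0.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class FakeRng:
    """Deterministic stand-in for a Generator: every draw equals its mean
    (gamma) or a scripted value (uniform draws)."""

    def __init__(self, uniform_values=(0.0,)):
        self._uniform = list(uniform_values)

    def random(self):
        return self._uniform.pop(0) if len(self._uniform) > 1 else self._uniform[0]

    def gamma(self, shape, scale):
        return shape * scale

    def lognormal(self, mu, sigma):
        return float(np.exp(mu + sigma * sigma / 2.0))
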