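"""Road graph, time-dependent ambulance speeds, and shortest-time routing.

The road network is a (by default undirected) graph whose nodes carry planar
coordinates in kilometres and a built-up flag, and whose edges carry a length
in kilometres and a road category (``highway``, ``main``, ``local``).  Travel
speed depends on the road category, whether the edge runs through a built-up
area, the priority of the call the ambulance is responding to, and the time of
day (rush hour vs. off-peak).  Routing minimises travel *time*; the speed of
each edge is frozen at the moment the ambulance enters it.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

CATEGORIES = ("highway", "main", "local")
PRIORITIES = ("K", "N", "M")
MINUTES_PER_DAY = 1440.0


class RoutingError(Exception):
    """No route exists between two nodes."""


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


@dataclass
class RoadNetwork:
    """Road graph with node coordinates (km), built-up flags and edge lengths."""

    graph: nx.Graph
    directed: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_frames(
        cls, nodes: pd.DataFrame, edges: pd.DataFrame, directed: bool = False
    ) -> "RoadNetwork":
        """Build from node/edge tables.

        ``nodes``: columns node_id, x_km, y_km, built_up.
        ``edges``: columns a, b, length_km, category.
        """
        g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
        for row in nodes.itertuples(index=False):
            g.add_node(
                row.node_id,
                x_km=float(row.x_km),
                y_km=float(row.y_km),
                built_up=bool(row.built_up),
            )
        for row in edges.itertuples(index=False):
            g.add_edge(row.a, row.b, length_km=float(row.length_km), category=row.category)
        return cls(g, directed=directed)

    @classmethod
    def read_csv(cls, nodes_path, edges_path, directed: bool = False) -> "RoadNetwork":
        return cls.from_frames(
            pd.read_csv(nodes_path, float_precision="round_trip"),
            pd.read_csv(edges_path, float_precision="round_trip"),
            directed,
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        nodes = pd.DataFrame(
            [
                {
                    "node_id": n,
                    "x_km": d["x_km"],
                    "y_km": d["y_km"],
                    "built_up": d["built_up"],
                }
                for n, d in sorted(self.graph.nodes(data=True))
            ]
        )
        edges = pd.DataFrame(
            [
                {"a": a, "b": b, "length_km": d["length_km"], "category": d["category"]}
                for a, b, d in sorted(self.graph.edges(data=True))
            ]
        )
        return nodes, edges

    def write_csv(self, nodes_path, edges_path) -> None:
        nodes, edges = self.to_frames()
        # %.17g keeps doubles exactly round-trippable through the CSV
        nodes.to_csv(nodes_path, index=False, float_format="%.17g")
        edges.to_csv(edges_path, index=False, float_format="%.17g")

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for a, b, d in self.graph.edges(data=True):
            if d["length_km"] <= 0:
                raise ValueError(f"edge ({a},{b}) has non-positive length")
            if d["category"] not in CATEGORIES:
                raise ValueError(f"edge ({a},{b}) has unknown category {d['category']!r}")
        for n, d in self.graph.nodes(data=True):
            if "x_km" not in d or "y_km" not in d:
                raise ValueError(f"node {n} lacks coordinates")

    # -- helpers ------------------------------------------------------------

    def coords(self, node) -> tuple[float, float]:
        d = self.graph.nodes[node]
        return d["x_km"], d["y_km"]

    def edge_built_up(self, a, b) -> bool:
        # an edge is treated as built-up when both of its endpoints are
        return bool(self.graph.nodes[a]["built_up"] and self.graph.nodes[b]["built_up"])

    def nearest_node(self, x_km: float, y_km: float, candidates: Iterable | None = None):
        """Euclidean-nearest node; deterministic lowest-id tie-break."""
        best = None
        best_key = None
        nodes = candidates if candidates is not None else self.graph.nodes
        for n in nodes:
            nx_, ny_ = self.coords(n)
            d2 = (nx_ - x_km) ** 2 + (ny_ - y_km) ** 2
            key = (d2, n)
            if best_key is None or key < best_key:
                best, best_key = n, key
        return best, float(np.sqrt(best_key[0]))


# ---------------------------------------------------------------------------
# speed model
# ---------------------------------------------------------------------------

DEFAULT_BASE_SPEEDS: dict[str, tuple[float, float]] = {
    # km/h, (off-peak, rush)
    "highway": (90.0, 72.0),
    "main": (60.0, 48.0),
    "local": (40.0, 32.0),
}
DEFAULT_PRIORITY_FACTORS = {"K": 1.0, "N": 1.0, "M": 0.9}
DEFAULT_RUSH_WINDOWS = ((390.0, 540.0), (900.0, 1080.0))  # 06:30-09:00, 15:00-18:00


@dataclass
class SpeedModel:
    """Travel-speed table keyed by (category, built-up, priority, time bucket).

    Speeds are stored as per-category (off-peak, rush) base values with a
    built-up multiplier and per-priority multipliers.  Rush-hour windows are
    minute-of-day half-open intervals.
    """

    base: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASE_SPEEDS)
    )
    built_up_factor: float = 0.8
    priority_factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRIORITY_FACTORS)
    )
    rush_windows: Sequence[tuple[float, float]] = DEFAULT_RUSH_WINDOWS

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for cat, (off, rush) in self.base.items():
            if off <= 0 or rush <= 0:
                raise ValueError(f"non-positive speed for {cat}")
            if rush > off:
                raise ValueError(f"rush speed exceeds off-peak speed for {cat}")
        if not 0 < self.built_up_factor <= 1:
            raise ValueError("built-up factor must be in (0, 1]")
        for p, f in self.priority_factors.items():
            if f <= 0:
                raise ValueError(f"non-positive priority factor for {p}")

    def is_rush(self, time_min: float) -> bool:
        tod = time_min % MINUTES_PER_DAY
        return any(a <= tod < b for a, b in self.rush_windows)

    def bucket(self, time_min: float) -> str:
        return "rush" if self.is_rush(time_min) else "offpeak"

    def speed(
        self,
        category: str,
        built_up: bool,
        priority: str,
        time_min: float | None = None,
        time_bucket: str | None = None,
    ) -> float:
        """Speed in km/h; bucket either from clock time or named explicitly."""
        if time_bucket is None:
            time_bucket = self.bucket(time_min if time_min is not None else 0.0)
        off, rush = self.base[category]
        s = rush if time_bucket == "rush" else off
        if built_up:
            s *= self.built_up_factor
        return s * self.priority_factors[priority]

    # -- yaml ---------------------------------------------------------------

    def to_yaml(self, path) -> None:
        payload = {
            "base": {k: list(v) for k, v in self.base.items()},
            "built_up_factor": self.built_up_factor,
            "priority_factors": dict(self.priority_factors),
            "rush_windows": [list(w) for w in self.rush_windows],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "SpeedModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            base={k: tuple(v) for k, v in payload["base"].items()},
            built_up_factor=payload["built_up_factor"],
            priority_factors=payload["priority_factors"],
            rush_windows=tuple(tuple(w) for w in payload["rush_windows"]),
        )


# ---------------------------------------------------------------------------
# routes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Route:
    """A node path with per-edge entry times (minutes) and lengths (km)."""

    nodes: tuple
    times: tuple  # arrival clock time at each node; times[0] is departure
    edge_lengths: tuple

    @property
    def depart_time(self) -> float:
        return self.times[0]

    @property
    def arrival_time(self) -> float:
        return self.times[-1]

    @property
    def total_time_min(self) -> float:
        return self.times[-1] - self.times[0]

    @property
    def total_length_km(self) -> float:
        return float(sum(self.edge_lengths))

    def length_to_index(self, k: int) -> float:
        """Cumulative driven distance at node index ``k``."""
        return float(sum(self.edge_lengths[:k]))


@dataclass(frozen=True)
class RoutePosition:
    """Where along a route a vehicle is at a query time."""

    at_node: bool
    node: object = None  # terminal (or current) node when at_node
    edge: tuple | None = None  # (a, b) when mid-edge
    offset: float = 0.0  # fractional progress along the edge
    next_index: int = 0  # index into route.nodes of the next node to be reached


def _edge_minutes(network: RoadNetwork, speed_model: SpeedModel, a, b, priority, t) -> float:
    d = network.graph[a][b]
    s = speed_model.speed(d["category"], network.edge_built_up(a, b), priority, time_min=t)
    return d["length_km"] / s * 60.0


def shortest_route(
    network: RoadNetwork,
    speed_model: SpeedModel,
    origin,
    dest,
    priority: str = "K",
    depart_time: float = 0.0,
) -> Route:
    """Minimal-travel-time route; each edge's speed frozen at its entry time.

    Raises :class:`RoutingError` when ``dest`` is unreachable from ``origin``.
    """
    g = network.graph
    if origin not in g or dest not in g:
        raise RoutingError(f"unknown node in pair ({origin!r}, {dest!r})")
    if origin == dest:
        return Route((origin,), (depart_time,), ())

    # time-dependent Dijkstra on arrival times, deterministic (node id) tie-break
    arrival = {origin: depart_time}
    prev: dict = {}
    heap: list = [(depart_time, origin)]
    done: set = set()
    while heap:
        t, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if u == dest:
            break
        for v in sorted(g.neighbors(u)):
            if v in done:
                continue
            tv = t + _edge_minutes(network, speed_model, u, v, priority, t)
            if v not in arrival or tv < arrival[v] - 1e-12:
                arrival[v] = tv
                prev[v] = u
                heapq.heappush(heap, (tv, v))
    if dest not in done:
        raise RoutingError(f"no route from {origin!r} to {dest!r}")

    path = [dest]
    while path[-1] != origin:
        path.append(prev[path[-1]])
    path.reverse()
    times = [depart_time]
    lengths = []
    for a, b in zip(path, path[1:]):
        times.append(times[-1] + _edge_minutes(network, speed_model, a, b, priority, times[-1]))
        lengths.append(g[a][b]["length_km"])
    return Route(tuple(path), tuple(times), tuple(lengths))


def travel_time_matrix(
    network: RoadNetwork,
    speed_model: SpeedModel,
    origins: Sequence,
    dests: Sequence,
    priority: str = "K",
    time_bucket: str = "offpeak",
    apply_built_up: bool = False,
) -> np.ndarray:
    """Static shortest-travel-time matrix t_ij in minutes.

    A single static speed context feeds the location model: a fixed time
    bucket and priority, with the built-up penalty optionally disabled
    (the default, so that the matrix reflects free-flow emergency driving).
    Raises :class:`RoutingError` on any unroutable pair rather than storing
    an infinite sentinel.
    """
    g = network.graph
    weighted = nx.DiGraph() if network.directed else nx.Graph()
    weighted.add_nodes_from(g.nodes)
    for a, b, d in g.edges(data=True):
        built = network.edge_built_up(a, b) if apply_built_up else False
        s = speed_model.speed(d["category"], built, priority, time_bucket=time_bucket)
        weighted.add_edge(a, b, minutes=d["length_km"] / s * 60.0)
    mat = np.empty((len(origins), len(dests)))
    for i, o in enumerate(origins):
        dist = nx.single_source_dijkstra_path_length(weighted, o, weight="minutes")
        for j, dnode in enumerate(dests):
            if dnode not in dist:
                raise RoutingError(f"no route from {o!r} to {dnode!r}")
            mat[i, j] = dist[dnode]
    return mat


def position_en_route(route: Route, query_time: float) -> RoutePosition:
    """Vehicle position along ``route`` at ``query_time``.

    Progress along the current edge is linear in time (constant frozen speed
    per edge).  Querying before departure violates the contract.
    """
    if query_time < route.depart_time - 1e-9:
        raise ValueError("query_time precedes route departure")
    if query_time >= route.arrival_time or len(route.nodes) == 1:
        last = len(route.nodes) - 1
        return RoutePosition(at_node=True, node=route.nodes[-1], next_index=last)
    times = route.times
    # locate segment k with times[k] <= q < times[k+1]
    k = int(np.searchsorted(np.asarray(times), query_time, side="right") - 1)
    k = max(k, 0)
    if abs(query_time - times[k]) < 1e-12:
        return RoutePosition(at_node=True, node=route.nodes[k], next_index=k)
    frac = (query_time - times[k]) / (times[k + 1] - times[k])
    return RoutePosition(
        at_node=False,
        edge=(route.nodes[k], route.nodes[k + 1]),
        offset=float(frac),
        next_index=k + 1,
    )


def divert_point(route: Route, now: float) -> tuple[object, float, float]:
    """Re-dispatch anchor for a vehicle travelling along ``route``.

    Returns ``(node, time_at_node, distance_km_from_route_start_to_node)``:
    the next node the vehicle can reach (it must finish its current edge), the
    clock time it gets there, and the distance driven along the route through
    that node.  A vehicle sitting exactly on a node diverts from that node at
    once.
    """
    pos = position_en_route(route, now)
    if pos.at_node:
        k = pos.next_index
        return route.nodes[k], max(now, route.times[k]), route.length_to_index(k)
    k = pos.next_index
    return route.nodes[k], route.times[k], route.length_to_index(k)
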