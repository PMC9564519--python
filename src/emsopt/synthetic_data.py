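"""Self-contained synthetic country generator.

Builds a random but reproducible mixed urban-rural world — road network,
municipalities with heavy-tailed populations, a tiered station deployment,
hospitals, and the call-arrival distribution — with the statistical structure
the analysis assumes: a bimodal hour-of-day arrival profile (morning peak
9-11, evening peak 18-21), on-scene means in the 20-30 min band (BLS above
ALS), hospital drop-off Erlang means between 14 and 38 min, and transport
probabilities of 0.71 (BLS) and 0.53 (ALS).  Every quantity is drawn from a
single seed, so the same configuration always yields the same country.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .demand_model import CallDistribution, DemandZone, sample_call_stream
from .road_network import RoadNetwork
from .simulator import Hospital, Station

#: hour-of-day shape of the arrival rate (relative weights, normalised later):
#: overnight trough, morning peak 9-11, evening peak 18-21
HOURLY_SHAPE = np.array(
    [
        0.55, 0.45, 0.40, 0.40, 0.45, 0.55,  # 0-5
        0.75, 0.95, 1.20, 1.60, 1.65, 1.45,  # 6-11
        1.20, 1.10, 1.05, 1.05, 1.10, 1.20,  # 12-17
        1.50, 1.55, 1.45, 1.20, 0.95, 0.70,  # 18-23
    ]
)

DEFAULT_PRIORITY_MIX = {"K": 0.12, "N": 0.55, "M": 0.33}
DEFAULT_DIAGNOSIS_PROBS = {
    # First Hour Quintet
    "chest_pain": 0.10,
    "severe_trauma": 0.05,
    "stroke": 0.06,
    "severe_respiratory": 0.06,
    "cardiac_arrest": 0.02,
    # other frequent reasons for dispatch
    "abdominal_pain": 0.12,
    "fall": 0.16,
    "intoxication": 0.08,
    "psychiatric": 0.07,
    "other": 0.28,
}
DEFAULT_AGE_PROBS = {"adult": 0.88, "child": 0.12}


class CountryConfigError(Exception):
    pass


@dataclass
class CountryConfig:
    """Knobs of the synthetic country.

    ``daily_calls_per_1000`` calibrates total call volume (all priorities) to
    population; ``n_towns`` municipalities (the most populous) receive a
    250 m street grid and count as urban.
    """

    n_municipalities: int = 12
    total_population: float = 150_000.0
    n_stations: int = 8  # one station per ~19k inhabitants, the national ratio
    als_share: float = 0.3
    n_hospitals: int = 2
    n_towns: int = 1
    town_grid_side: int = 5  # street grid is side x side nodes, 0.25 km apart
    area_side_km: float = 45.0
    road_winding: float = 1.25  # detour factor on straight-line intercity distance
    daily_calls_per_1000: float = 0.13
    priority_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PRIORITY_MIX))
    diagnosis_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIAGNOSIS_PROBS)
    )
    age_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_PROBS))
    pop_lognorm_sigma: float = 1.1
    max_stations_per_municipality: int = 6
    #: how far the current deployment has drifted from today's demand: the
    #: apportionment weights are population times lognormal(0, sigma) noise,
    #: emulating a historically grown network that no longer matches demand
    station_misalignment: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 1:
            raise CountryConfigError("need at least one station")
        if not 0 < self.als_share < 1:
            raise CountryConfigError("ALS share must be in (0, 1)")
        if self.n_towns > self.n_municipalities:
            raise CountryConfigError("more towns than municipalities")
        if self.n_stations > self.n_municipalities * self.max_stations_per_municipality:
            raise CountryConfigError(
                "unsatisfiable config: more stations than municipalities can host"
            )
        if self.n_hospitals > self.n_municipalities:
            raise CountryConfigError("more hospitals than municipalities")


@dataclass
class Country:
    """Everything the optimizer and simulator need, generated from one seed."""

    config: CountryConfig
    network: RoadNetwork
    zones: list[DemandZone]
    stations: list[Station]
    hospitals: list[Hospital]
    call_dist: CallDistribution
    municipalities: pd.DataFrame  # id, node, x_km, y_km, population, urban
    node_populations: dict
    town_extents: dict

    @property
    def central_nodes(self) -> dict:
        return dict(zip(self.municipalities["id"], self.municipalities["node"]))

    @property
    def urban_map(self) -> dict:
        return {
            r.id: ("urban" if r.urban else "rural")
            for r in self.municipalities.itertuples(index=False)
        }


def _largest_remainder(weights: np.ndarray, total: int, cap) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``.

    ``cap`` is a scalar or per-entry array of upper limits.
    """
    cap = np.broadcast_to(np.asarray(cap, dtype=int), weights.shape).copy()
    quota = weights / weights.sum() * total
    base = np.minimum(np.floor(quota).astype(int), cap)
    rest = total - base.sum()
    frac = quota - np.floor(quota)
    order = sorted(range(len(frac)), key=lambda i: (-frac[i], i))
    for i in order:
        if rest == 0:
            break
        if base[i] < cap[i]:
            base[i] += 1
            rest -= 1
    if rest > 0:  # caps bind; spread anywhere with room
        for i in range(len(base)):
            while rest > 0 and base[i] < cap[i]:
                base[i] += 1
                rest -= 1
    return base


def generate_country(config: CountryConfig) -> Country:
    """Generate the synthetic country; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_municipalities
    side = config.area_side_km

    # municipality centres with a minimum separation (simple rejection)
    min_sep = side / (2.5 * np.sqrt(max(n, 2)))
    pts: list[tuple[float, float]] = []
    while len(pts) < n:
        cand = rng.uniform(0, side, size=2)
        if all((cand[0] - x) ** 2 + (cand[1] - y) ** 2 >= min_sep**2 for x, y in pts):
            pts.append((float(cand[0]), float(cand[1])))
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])

    # heavy-tailed populations scaled to the configured total
    raw = rng.lognormal(mean=0.0, sigma=config.pop_lognorm_sigma, size=n)
    pops = raw / raw.sum() * config.total_population
    town_idx = set(np.argsort(-pops)[: config.n_towns].tolist())

    nodes = [
        {"node_id": i, "x_km": xs[i], "y_km": ys[i], "built_up": i in town_idx}
        for i in range(n)
    ]
    edges: list[dict] = []

    def add_edge(a, b, length, category):
        edges.append({"a": a, "b": b, "length_km": max(length, 0.05), "category": category})

    # intercity edges: Euclidean MST plus 2-nearest-neighbour shortcuts
    if n > 1:
        d2 = (xs[:, None] - xs[None, :]) ** 2 + (ys[:, None] - ys[None, :]) ** 2
        dist = np.sqrt(d2)
        mst = minimum_spanning_tree(dist).tocoo()
        pair_set: set[tuple[int, int]] = {
            (min(int(a), int(b)), max(int(a), int(b))) for a, b in zip(mst.row, mst.col)
        }
        for a in range(n):
            for b in np.argsort(dist[a])[1:3]:
                pair_set.add((min(a, int(b)), max(a, int(b))))
        for a, b in sorted(pair_set):
            if a in town_idx and b in town_idx:
                cat = "highway"
            elif a in town_idx or b in town_idx or dist[a, b] > 0.35 * side:
                cat = "main"
            else:
                cat = "local"
            add_edge(a, b, dist[a, b] * config.road_winding, cat)

    # street grids inside towns
    next_id = n
    zone_nodes: dict[int, list[int]] = {i: [i] for i in range(n)}
    node_populations: dict[int, float] = {}
    town_extents: dict[str, tuple] = {}
    g = config.town_grid_side
    for ti in sorted(town_idx):
        cx, cy = xs[ti], ys[ti]
        half = (g - 1) / 2 * 0.25
        town_extents[f"M{ti:02d}"] = (cx - half - 0.125, cy - half - 0.125,
                                      cx + half + 0.125, cy + half + 0.125)
        grid_ids = {}
        for gy in range(g):
            for gx in range(g):
                x = cx - half + gx * 0.25
                y = cy - half + gy * 0.25
                nid = next_id
                next_id += 1
                grid_ids[(gx, gy)] = nid
                nodes.append({"node_id": nid, "x_km": x, "y_km": y, "built_up": True})
                zone_nodes[ti].append(nid)
        for (gx, gy), nid in grid_ids.items():
            if gx + 1 < g:
                add_edge(nid, grid_ids[(gx + 1, gy)], 0.25, "local")
            if gy + 1 < g:
                add_edge(nid, grid_ids[(gx, gy + 1)], 0.25, "local")
        # tie the grid to the municipality centre node
        centre_grid = grid_ids[((g - 1) // 2, (g - 1) // 2)]
        add_edge(ti, centre_grid, 0.05, "local")
        # centre-weighted distribution of the town's population over its grid
        weights = np.array(
            [
                np.exp(-((gx - (g - 1) / 2) ** 2 + (gy - (g - 1) / 2) ** 2) / (g / 2))
                for (gx, gy) in sorted(grid_ids)
            ]
        )
        shares = weights / weights.sum() * pops[ti]
        for (key, share) in zip(sorted(grid_ids), shares):
            node_populations[grid_ids[key]] = float(share)
    for i in range(n):
        if i not in town_idx:
            node_populations[i] = float(pops[i])

    network = RoadNetwork.from_frames(pd.DataFrame(nodes), pd.DataFrame(edges))

    zones = [
        DemandZone(
            id=f"M{i:02d}",
            level="municipality",
            anchor_node=i,
            population=float(pops[i]),
            nodes=tuple(zone_nodes[i]),
            center=(float(xs[i]), float(ys[i])),
        )
        for i in range(n)
    ]

    # stations: apportioned to municipalities by population distorted with
    # misalignment noise (the current network grew historically and lags the
    # present demand), every station at its municipality's central node
    station_weights = pops * rng.lognormal(0.0, config.station_misalignment, size=n)
    # multiple stations per municipality only in towns, as in the real system
    caps = np.array(
        [config.max_stations_per_municipality if i in town_idx else 1 for i in range(n)]
    )
    counts = _largest_remainder(station_weights, config.n_stations, caps)
    n_als = min(max(int(round(config.als_share * config.n_stations)), 1),
                config.n_stations - 1)
    als_counts = _largest_remainder(np.where(counts > 0, station_weights, 0.0), n_als, caps)
    als_counts = np.minimum(als_counts, counts)
    short = n_als - als_counts.sum()
    if short > 0:  # top up where BLS stations remain, largest municipality first
        for i in np.argsort(-pops):
            room = counts[i] - als_counts[i]
            take = min(room, short)
            als_counts[i] += take
            short -= take
            if short == 0:
                break
    stations = []
    sid = 0
    for i in range(n):
        for k in range(counts[i]):
            kind = "ALS" if k < als_counts[i] else "BLS"
            stations.append(
                Station(id=f"S{sid:03d}", node=i, kind=kind, municipality=f"M{i:02d}")
            )
            sid += 1

    # hospitals in the most populous municipalities
    hospitals = []
    order = np.argsort(-pops)[: config.n_hospitals]
    for rank, i in enumerate(order):
        admits = "both" if rank == 0 else ("adults" if rank % 2 == 1 else "both")
        hospitals.append(
            Hospital(
                id=f"H{rank:02d}",
                node=int(i),
                admits=admits,
                specializations=None,
                dropoff_mean_min=float(rng.uniform(14.0, 38.0)),
                dropoff_shape=3,
            )
        )

    daily = config.total_population / 1000.0 * config.daily_calls_per_1000
    hourly = HOURLY_SHAPE / HOURLY_SHAPE.sum() * daily
    call_dist = CallDistribution(
        hourly_rates=hourly,
        priority_mix=dict(config.priority_mix),
        diagnosis_probs=dict(config.diagnosis_probs),
        age_probs=dict(config.age_probs),
    )

    municipalities = pd.DataFrame(
        [
            {
                "id": f"M{i:02d}",
                "node": i,
                "x_km": float(xs[i]),
                "y_km": float(ys[i]),
                "population": float(pops[i]),
                "urban": i in town_idx,
            }
            for i in range(n)
        ]
    )
    return Country(
        config=config,
        network=network,
        zones=zones,
        stations=stations,
        hospitals=hospitals,
        call_dist=call_dist,
        municipalities=municipalities,
        node_populations=node_populations,
        town_extents=town_extents,
    )


def generate_call_history(
    country: Country, days: float, seed: int
) -> pd.DataFrame:
    """Synthetic historical call record in the calls CSV dialect."""
    if days == 0:
        return pd.DataFrame(
            columns=["time_min", "zone_id", "node", "priority", "diagnosis", "age_class"]
        )
    return sample_call_stream(
        country.call_dist, country.zones, days, np.random.default_rng(seed)
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def tiny_config(seed: int = 0) -> CountryConfig:
    """Desk-scale world: full pipeline runs in seconds."""
    return CountryConfig(seed=seed)


def slovakia_like_config(seed: int = 0) -> CountryConfig:
    """Country with the published Slovak summary shape.

    274 stations of which 86 ALS, 8 towns with street grids, 5.4 M
    inhabitants.  The municipality count is far below the real 2934-node
    demand set; this preset reproduces scale ratios, not geography.
    """
    return CountryConfig(
        n_municipalities=320,
        total_population=5_400_000.0,
        n_stations=274,
        als_share=86 / 274,
        n_hospitals=12,
        n_towns=8,
        area_side_km=320.0,
        seed=seed,
    )
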