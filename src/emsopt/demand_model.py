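"""Spatial and temporal demand representation for EMS calls.

Demand is represented at two levels: one zone per municipality nationwide,
and 250 m square grid cells inside towns selected for within-town
optimization.  Zone weights are counts of historical life-threatening (K)
and urgent (N) calls; non-urgent (M) calls contribute to simulated traffic
but not to the location model's demand.  Call arrivals follow a
non-homogeneous Poisson process with an hour-of-day rate profile; day-of-week
and month effects are treated as flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .road_network import RoadNetwork

PRIORITIES = ("K", "N", "M")

#: the First Hour Quintet: the most time-critical diagnosis group
FHQ_DIAGNOSES = frozenset(
    {"chest_pain", "severe_trauma", "stroke", "severe_respiratory", "cardiac_arrest"}
)

AGE_CLASSES = ("adult", "child")

CALL_COLUMNS = ["time_min", "zone_id", "node", "priority", "diagnosis", "age_class"]


class DemandError(Exception):
    """A call record cannot be mapped to the demand representation."""


@dataclass
class DemandZone:
    """A demand zone: a whole municipality or one grid cell of a town.

    ``nodes`` lists the road nodes belonging to the zone (calls inside the
    zone are placed uniformly on them); ``anchor_node`` is the road node
    nearest the zone centre and is where the zone's demand weight sits in the
    location model.
    """

    id: str
    level: str  # "municipality" | "grid_cell"
    anchor_node: object
    population: float
    weight: float = 0.0  # b_j: count of K+N historical calls
    parent: str | None = None
    nodes: tuple = ()
    center: tuple[float, float] | None = None
    anchored: bool = True

    def __post_init__(self) -> None:
        if self.level not in ("municipality", "grid_cell"):
            raise ValueError(f"unknown zone level {self.level!r}")
        if self.population < 0 or self.weight < 0:
            raise ValueError("population and weight must be non-negative")
        if not self.nodes and self.anchor_node is not None:
            self.nodes = (self.anchor_node,)


@dataclass
class CallDistribution:
    """Temporal and attribute distributions of emergency calls.

    ``hourly_rates`` are expected calls per hour of day for the whole region
    (length 24, calls/hour).  Attribute distributions are categorical and
    must each sum to one.
    """

    hourly_rates: np.ndarray
    priority_mix: Mapping[str, float]
    diagnosis_probs: Mapping[str, float]
    age_probs: Mapping[str, float]

    def __post_init__(self) -> None:
        self.hourly_rates = np.asarray(self.hourly_rates, dtype=float)
        if self.hourly_rates.shape != (24,):
            raise ValueError("hourly_rates must have 24 entries")
        if np.any(self.hourly_rates < 0):
            raise ValueError("negative hourly rate")
        for name, dist in (
            ("priority_mix", self.priority_mix),
            ("diagnosis_probs", self.diagnosis_probs),
            ("age_probs", self.age_probs),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, expected 1")
            if any(v < 0 for v in dist.values()):
                raise ValueError(f"{name} has negative probabilities")

    @property
    def daily_rate(self) -> float:
        return float(self.hourly_rates.sum())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def aggregate_demand(
    calls: pd.DataFrame, zones: Sequence[DemandZone], by: str = "zone_id"
) -> dict[str, float]:
    """Zone weights b_j = count of priority K and N calls per zone.

    ``by="zone_id"`` matches on the call's recorded zone; ``by="node"``
    assigns a call to the zone whose ``nodes`` contain its road node (used for
    grid cells, whose ids the raw history does not carry).  A call that maps
    to no zone is an error.
    """
    weights = {z.id: 0.0 for z in zones}
    if by == "node":
        node_to_zone: dict = {}
        for z in zones:
            for n in z.nodes:
                node_to_zone.setdefault(n, z.id)
    kn = calls[calls["priority"].isin(["K", "N"])]
    for row in kn.itertuples(index=False):
        if by == "zone_id":
            zid = row.zone_id
            if zid not in weights:
                raise DemandError(f"call in unknown zone: {row}")
        else:
            zid = node_to_zone.get(row.node)
            if zid is None:
                raise DemandError(f"call at node outside every zone: {row}")
        weights[zid] += 1.0
    return weights


def make_grid_zones(
    extent: tuple[float, float, float, float],
    network: RoadNetwork,
    town_id: str,
    cell_size_km: float = 0.25,
    node_populations: Mapping | None = None,
    candidate_nodes: Sequence | None = None,
    snap_radius_km: float = 1.0,
    drop_empty: bool = False,
) -> list[DemandZone]:
    """Tile a town extent with square cells and anchor each to the road graph.

    ``extent`` is (xmin, ymin, xmax, ymax) in km.  Each cell's anchor is the
    Euclidean-nearest road node to the cell centre (among ``candidate_nodes``
    when given, typically the town's street nodes).  Cells whose nearest node
    is farther than ``snap_radius_km`` are flagged unanchored; with
    ``drop_empty`` cells with zero population are dropped.
    """
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("empty town extent")
    nx_cells = int(np.ceil((xmax - xmin) / cell_size_km - 1e-9))
    ny_cells = int(np.ceil((ymax - ymin) / cell_size_km - 1e-9))
    cand = list(candidate_nodes) if candidate_nodes is not None else None
    node_pop = dict(node_populations or {})

    def nodes_in_cell(x0, y0, x1, y1):
        pool = cand if cand is not None else network.graph.nodes
        out = []
        for n in pool:
            x, y = network.coords(n)
            if x0 <= x < x1 and y0 <= y < y1:
                out.append(n)
        return sorted(out)

    zones: list[DemandZone] = []
    for iy in range(ny_cells):
        for ix in range(nx_cells):
            x0, y0 = xmin + ix * cell_size_km, ymin + iy * cell_size_km
            x1, y1 = x0 + cell_size_km, y0 + cell_size_km
            cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
            anchor, dist = network.nearest_node(cx, cy, candidates=cand)
            anchored = dist <= snap_radius_km
            members = nodes_in_cell(x0, y0, x1, y1)
            pop = float(sum(node_pop.get(n, 0.0) for n in members))
            if drop_empty and pop == 0.0 and not members:
                continue
            zones.append(
                DemandZone(
                    id=f"{town_id}_c{ix}_{iy}",
                    level="grid_cell",
                    anchor_node=anchor if anchored else None,
                    population=pop,
                    parent=town_id,
                    nodes=tuple(members) or ((anchor,) if anchored else ()),
                    center=(cx, cy),
                    anchored=anchored,
                )
            )
    return zones


def estimate_hourly_rates(calls: pd.DataFrame, horizon_days: float) -> np.ndarray:
    """Hourly arrival rates lambda_h (calls per day-hour) from a call stream."""
    if horizon_days <= 0:
        raise ValueError("horizon_days must be positive")
    rates = np.zeros(24)
    if len(calls):
        hours = (calls["time_min"].to_numpy() // 60).astype(int) % 24
        counts = np.bincount(hours, minlength=24)
        rates = counts / horizon_days
    return rates


def sample_call_stream(
    dist: CallDistribution,
    zones: Sequence[DemandZone],
    horizon_days: float,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Draw a time-ordered synthetic call stream over ``horizon_days``.

    Arrivals are a piecewise-homogeneous Poisson process (per-hour Poisson
    counts with uniform order statistics inside each hour).  Each call is
    assigned to a zone with probability proportional to population, to a road
    node uniformly within the zone, and attributes are drawn independently
    from the configured categorical distributions.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    pops = np.array([z.population for z in zones], dtype=float)
    if pops.sum() <= 0:
        raise ValueError("zones carry no population")
    zone_p = pops / pops.sum()
    prio_names = sorted(dist.priority_mix)
    prio_p = np.array([dist.priority_mix[k] for k in prio_names])
    diag_names = sorted(dist.diagnosis_probs)
    diag_p = np.array([dist.diagnosis_probs[k] for k in diag_names])
    age_names = sorted(dist.age_probs)
    age_p = np.array([dist.age_probs[k] for k in age_names])

    rows = []
    n_hours = int(round(horizon_days * 24))
    for h in range(n_hours):
        lam = dist.hourly_rates[h % 24]
        count = rng.poisson(lam) if lam > 0 else 0
        if count == 0:
            continue
        times = np.sort(rng.uniform(0.0, 60.0, size=count)) + h * 60.0
        zidx = rng.choice(len(zones), size=count, p=zone_p)
        prio = rng.choice(prio_names, size=count, p=prio_p)
        diag = rng.choice(diag_names, size=count, p=diag_p)
        age = rng.choice(age_names, size=count, p=age_p)
        for t, zi, pr, dg, ag in zip(times, zidx, prio, diag, age):
            z = zones[zi]
            node = z.nodes[rng.integers(len(z.nodes))]
            rows.append((float(t), z.id, node, pr, dg, ag))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------


def write_calls_csv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, index=False)


def read_calls_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise DemandError(f"calls file lacks columns {sorted(missing)}")
    return df


def write_zones_csv(zones: Sequence[DemandZone], path) -> None:
    pd.DataFrame(
        [
            {
                "id": z.id,
                "level": z.level,
                "anchor_node": z.anchor_node,
                "population": z.population,
                "weight": z.weight,
                "parent": z.parent,
                "nodes": ";".join(str(n) for n in z.nodes),
            }
            for z in zones
        ]
    ).to_csv(path, index=False)


def read_zones_csv(path, node_type=int) -> list[DemandZone]:
    df = pd.read_csv(path)
    zones = []
    for row in df.itertuples(index=False):
        nodes = tuple(node_type(s) for s in str(row.nodes).split(";") if s != "")
        zones.append(
            DemandZone(
                id=str(row.id),
                level=row.level,
                anchor_node=node_type(row.anchor_node),
                population=float(row.population),
                weight=float(row.weight),
                parent=None if pd.isna(row.parent) else str(row.parent),
                nodes=nodes,
            )
        )
    return zones
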