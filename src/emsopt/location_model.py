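"""Hierarchical pq-median station-location model with fixing rules.

The lower level chooses ``p`` station sites minimising the demand-weighted
total travel time from each demand zone to its nearest open site.  The upper
level then selects ``q`` of those sites for advanced-life-support (ALS)
ambulances, again minimising demand-weighted travel time; the two tiers'
catchment areas need not nest (a non-coherent hierarchy).  Both levels are
solved to proven optimality as mixed-integer programs (HiGHS via
``scipy.optimize.milp``).

Pre-processing fixes stations in high-demand towns (capacity rule) and in
small towns that currently operate two stations (small-town rule), and a
relocation budget bounds how many of the free stations may move to new
municipalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

UNRESTRICTED = "unrestricted"


class InfeasibleInstanceError(Exception):
    """The location instance admits no feasible station placement."""


class SolverError(Exception):
    """The MIP backend failed to prove optimality."""


# ---------------------------------------------------------------------------
# instance / solution containers
# ---------------------------------------------------------------------------


@dataclass
class LocationInstance:
    """All inputs of the two-level location model.

    ``t`` is the |I| x |J| travel-time matrix in minutes, ``b`` the demand
    weights, ``p`` the total number of open sites and ``q`` the number of ALS
    sites among them.  ``fixed_open`` are candidate indices forced open by the
    fixing rules (``fixed_als`` the subset whose ALS type is immutable);
    ``current_sites`` are candidates currently hosting a free station, and
    ``relocation_budget`` caps how many free stations may leave them
    (``None`` = unrestricted).
    """

    candidates: Sequence  # I, candidate node ids
    zones: Sequence  # J, zone ids
    t: np.ndarray
    b: np.ndarray
    p: int
    q: int
    fixed_open: frozenset = frozenset()  # subset of candidates
    fixed_als: frozenset = frozenset()
    current_sites: frozenset = frozenset()  # free-station sites, disjoint from fixed_open
    relocation_budget: int | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.fixed_open = frozenset(self.fixed_open)
        self.fixed_als = frozenset(self.fixed_als)
        self.current_sites = frozenset(self.current_sites)
        n, m = len(self.candidates), len(self.zones)
        if self.t.shape != (n, m):
            raise ValueError(f"t has shape {self.t.shape}, expected ({n}, {m})")
        if self.b.shape != (m,):
            raise ValueError("b length mismatch")
        if np.any(self.t < 0) or np.any(self.b < 0):
            raise ValueError("t and b must be non-negative")
        if not (0 < self.q <= self.p <= n):
            raise ValueError(f"need 0 < q <= p <= |I| (got q={self.q}, p={self.p}, |I|={n})")
        cand = set(self.candidates)
        if not self.fixed_open <= cand:
            raise ValueError("fixed_open not a subset of candidates")
        if not self.fixed_als <= self.fixed_open:
            raise ValueError("fixed_als not a subset of fixed_open")
        if len(self.fixed_open) > self.p:
            raise ValueError("more fixed sites than p")
        if len(self.fixed_als) > self.q:
            raise ValueError("more fixed ALS sites than q")
        if self.relocation_budget is not None and self.relocation_budget < 0:
            raise ValueError("relocation budget must be non-negative")

    @property
    def p_free(self) -> int:
        return self.p - len(self.fixed_open)

    def index_of(self, site) -> int:
        return list(self.candidates).index(site)


@dataclass
class LocationSolution:
    """Solved station placement: open sites, ALS sites and assignments."""

    open_sites: tuple
    assignment: dict  # zone id -> site id (nearest open, lowest-id tie-break)
    z_low: float
    als_sites: tuple = ()
    als_assignment: dict = field(default_factory=dict)
    z_up: float | None = None

    def __post_init__(self) -> None:
        if self.als_sites and not set(self.als_sites) <= set(self.open_sites):
            raise ValueError("ALS sites must be a subset of open sites")


@dataclass
class FixingReport:
    """Outcome of the station-fixing rules applied before optimization.

    ``capacity`` is the average population served by one station.  Each town
    row records how many stations were fixed, which rule fired (1, 2, or 0),
    and the fraction by which the town's demand weight is retained after the
    fixed stations absorb their share.
    """

    capacity: float
    towns: pd.DataFrame  # municipality, n_stations, population, n_fixed, rule, demand_scale
    fixed_station_ids: tuple
    fixed_als_station_ids: tuple

    @property
    def total_fixed(self) -> int:
        return int(self.towns["n_fixed"].sum())

    def demand_scale(self, municipality) -> float:
        rows = self.towns[self.towns["municipality"] == municipality]
        return float(rows["demand_scale"].iloc[0]) if len(rows) else 1.0


# ---------------------------------------------------------------------------
# pre-processing
# ---------------------------------------------------------------------------


def apply_fixing_rules(
    stations: pd.DataFrame,
    town_populations: Mapping[str, float],
    total_population: float,
) -> FixingReport:
    """Fix stations at their current positions in towns that need them.

    Capacity C = total population / total station count.  Rule 1 (capacity
    rule): a town with k stations and population P keeps all k fixed when
    P > kC; otherwise n = floor(P/C) stations are fixed and the town's demand
    weight is scaled by 1 - nC/P.  Rule 2 (small-town rule): a town with
    exactly two stations and P < C, where rule 1 fixed none, keeps one.
    Within a town, ALS stations are fixed first, then ascending station id.
    """
    required = {"id", "municipality", "type"}
    if not required <= set(stations.columns):
        raise ValueError(f"stations table needs columns {sorted(required)}")
    unknown = set(stations["municipality"]) - set(town_populations)
    if unknown:
        raise ValueError(f"stations in unknown towns: {sorted(map(str, unknown))}")

    capacity = float(total_population) / len(stations)
    rows = []
    fixed_ids: list = []
    fixed_als_ids: list = []
    for town, group in stations.groupby("municipality", sort=True):
        k = len(group)
        pop = float(town_populations[town])
        if pop > k * capacity:
            n_fixed, rule, scale = k, 1, 1.0
        else:
            n = math.floor(pop / capacity)
            if n > 0:
                n_fixed, rule, scale = n, 1, 1.0 - n * capacity / pop
            elif k == 2:
                n_fixed, rule, scale = 1, 2, 1.0
            else:
                n_fixed, rule, scale = 0, 0, 1.0
        ordered = group.sort_values(
            by=["type", "id"], key=lambda s: s.map(lambda v: 0 if v == "ALS" else 1)
            if s.name == "type"
            else s,
        )
        chosen = ordered.head(n_fixed)
        fixed_ids.extend(chosen["id"])
        fixed_als_ids.extend(chosen.loc[chosen["type"] == "ALS", "id"])
        rows.append(
            {
                "municipality": town,
                "n_stations": k,
                "population": pop,
                "n_fixed": n_fixed,
                "rule": rule,
                "demand_scale": scale,
            }
        )
    return FixingReport(
        capacity=capacity,
        towns=pd.DataFrame(rows),
        fixed_station_ids=tuple(fixed_ids),
        fixed_als_station_ids=tuple(fixed_als_ids),
    )


def build_scenario(
    total_station_count: int,
    fraction,
    free_station_count: int | None = None,
) -> int:
    """Relocation budget r for a redesign scenario.

    A numeric fraction in (0, 1] yields r = round(fraction * total stations);
    ``"unrestricted"`` lets every free station move (r = free station count).
    """
    if fraction == UNRESTRICTED:
        if free_station_count is None:
            raise ValueError("unrestricted scenario needs the free station count")
        return int(free_station_count)
    fraction = float(fraction)
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return int(round(fraction * total_station_count))


# ---------------------------------------------------------------------------
# MIP solves
# ---------------------------------------------------------------------------


def _nearest_assignment(t: np.ndarray, open_idx: Sequence[int]) -> np.ndarray:
    """Zone -> open-candidate-index, nearest with lowest-index tie-break."""
    sub = t[list(open_idx), :]  # (k, m)
    best = np.argmin(sub, axis=0)  # argmin returns first (lowest index) on ties
    return np.array([open_idx[k] for k in best])


def _assignment_cost(t: np.ndarray, b: np.ndarray, open_idx: Sequence[int]) -> float:
    return float(np.sum(t[list(open_idx), :].min(axis=0) * b))


def _solve_median_milp(
    t: np.ndarray,
    b: np.ndarray,
    p: int,
    forced_idx: Sequence[int],
    budget_idx: Sequence[int] | None = None,
    budget_min: int | None = None,
) -> tuple[list[int], float]:
    """Exact p-median over rows of ``t`` with forced-open and budget rows.

    Variables: y_i (binary), x_ij (continuous in [0,1]; integral at optimum
    because the assignment subproblem is a simple minimum once y is fixed).
    ``budget_idx``/``budget_min`` add  sum_{i in budget_idx} y_i >= budget_min.
    """
    n, m = t.shape
    nvar = n + n * m
    c = np.concatenate([np.zeros(n), (t * b[None, :]).ravel()])

    cons = []
    # each zone assigned exactly once
    rows, cols = [], []
    for j in range(m):
        for i in range(n):
            rows.append(j)
            cols.append(n + i * m + j)
    a_assign = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, nvar))
    cons.append(LinearConstraint(a_assign, 1.0, 1.0))
    # x_ij <= y_i  (disaggregated)
    rows, cols, vals = [], [], []
    for i in range(n):
        for j in range(m):
            r = i * m + j
            rows += [r, r]
            cols += [n + i * m + j, i]
            vals += [1.0, -1.0]
    a_link = sparse.csr_matrix((vals, (rows, cols)), shape=(n * m, nvar))
    cons.append(LinearConstraint(a_link, -np.inf, 0.0))
    # sum y = p
    a_card = sparse.csr_matrix((np.ones(n), (np.zeros(n, int), np.arange(n))), shape=(1, nvar))
    cons.append(LinearConstraint(a_card, p, p))
    if budget_idx is not None and budget_min is not None and budget_min > 0:
        a_bud = sparse.csr_matrix(
            (np.ones(len(budget_idx)), (np.zeros(len(budget_idx), int), list(budget_idx))),
            shape=(1, nvar),
        )
        cons.append(LinearConstraint(a_bud, budget_min, np.inf))

    lb = np.zeros(nvar)
    ub = np.ones(nvar)
    for i in forced_idx:
        lb[i] = 1.0
    integrality = np.concatenate([np.ones(n), np.zeros(n * m)])

    res = milp(
        c=c,
        constraints=cons,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"mip_rel_gap": 1e-9},
    )
    if res.status == 2:
        raise InfeasibleInstanceError(
            "no feasible placement (check fixed sites vs relocation budget)"
        )
    if not res.success:
        raise SolverError(f"MIP backend failed: {res.message}")
    y = res.x[:n]
    open_idx = sorted(np.flatnonzero(y > 0.5).tolist())
    if len(open_idx) != p:
        raise SolverError("solver returned a placement of the wrong cardinality")
    # canonical objective from the nearest-open assignment (removes LP ties)
    z = _assignment_cost(t, b, open_idx)
    if abs(z - res.fun) > 1e-6 * max(1.0, abs(z)):
        raise SolverError("assignment cost disagrees with MIP objective")
    return open_idx, z


def solve_lower_level(instance: LocationInstance) -> LocationSolution:
    """Optimal p-median placement honouring fixed sites and the budget.

    Returns a solution with ``open_sites`` of cardinality p, each zone
    assigned to its nearest open site (lowest site id on ties), and the
    proven-optimal objective ``z_low``.
    """
    cand = list(instance.candidates)
    idx = {s: i for i, s in enumerate(cand)}
    forced = sorted(idx[s] for s in instance.fixed_open)
    budget_idx = budget_min = None
    if instance.relocation_budget is not None:
        keep = instance.p_free - instance.relocation_budget
        if keep > 0:
            budget_idx = sorted(idx[s] for s in instance.current_sites)
            budget_min = keep
            if len(budget_idx) < keep:
                raise InfeasibleInstanceError(
                    f"budget requires keeping {keep} current sites but only "
                    f"{len(budget_idx)} exist"
                )
    open_idx, z = _solve_median_milp(
        instance.t, instance.b, instance.p, forced, budget_idx, budget_min
    )
    assign_idx = _nearest_assignment(instance.t, open_idx)
    assignment = {z_id: cand[a] for z_id, a in zip(instance.zones, assign_idx)}
    return LocationSolution(
        open_sites=tuple(cand[i] for i in open_idx), assignment=assignment, z_low=z
    )


def solve_upper_level(
    instance: LocationInstance, solution: LocationSolution
) -> LocationSolution:
    """Choose q ALS sites among the open sites (fixed ALS sites forced in).

    Fixed BLS stations may be upgraded to ALS; every non-fixed type is free.
    Returns the solution completed with ``als_sites``, the nearest-ALS
    assignment and the proven-optimal objective ``z_up``.
    """
    open_sites = list(solution.open_sites)
    if instance.q > len(open_sites):
        raise ValueError("q exceeds the number of open sites")
    missing = instance.fixed_als - set(open_sites)
    if missing:
        raise ValueError(f"fixed ALS sites not open: {sorted(map(str, missing))}")
    cand = list(instance.candidates)
    row = {s: cand.index(s) for s in open_sites}
    t_sub = instance.t[[row[s] for s in open_sites], :]
    forced = sorted(open_sites.index(s) for s in instance.fixed_als)
    open_idx, z_up = _solve_median_milp(t_sub, instance.b, instance.q, forced)
    als_sites = tuple(open_sites[i] for i in open_idx)
    assign_idx = _nearest_assignment(t_sub, open_idx)
    als_assignment = {z_id: open_sites[a] for z_id, a in zip(instance.zones, assign_idx)}
    return LocationSolution(
        open_sites=solution.open_sites,
        assignment=solution.assignment,
        z_low=solution.z_low,
        als_sites=als_sites,
        als_assignment=als_assignment,
        z_up=z_up,
    )


def solve(instance: LocationInstance) -> LocationSolution:
    """Both levels in sequence (lower-level sites feed the upper level)."""
    return solve_upper_level(instance, solve_lower_level(instance))


# ---------------------------------------------------------------------------
# post-processing and static indicators
# ---------------------------------------------------------------------------


@dataclass
class DeploymentPlan:
    """Final station placements derived from a solved instance.

    ``stations`` has columns id, node, municipality, type, moved_from
    (NaN when the station keeps its address).
    """

    stations: pd.DataFrame
    relocated_total: int
    relocated_by_type: dict
    type_switches: dict  # {"BLS_to_ALS": int, "ALS_to_BLS": int}


def postprocess_solution(
    solution: LocationSolution,
    current_stations: pd.DataFrame,
    site_municipality: Mapping,
    central_nodes: Mapping,
    fixed_station_ids: Sequence = (),
) -> DeploymentPlan:
    """Place stations at concrete addresses and count relocations.

    Stations that stay in their current municipality keep their current
    address node; relocated stations sit at the target municipality's central
    node.  A station counts as relocated iff its municipality differs from
    its origin's.  Site types come from the upper level (``als_sites``); when
    matching origin stations to relocated sites, same-type pairs are matched
    first so that type-switch counts are not inflated.
    """
    fixed_ids = set(fixed_station_ids)
    cur = current_stations.set_index("id", drop=False)
    als_sites = set(solution.als_sites)

    free_sites = [s for s in solution.open_sites]
    # municipality of each open site
    site_muni = {s: site_municipality[s] for s in solution.open_sites}

    placed_rows = []
    used_sites: set = set()
    # fixed stations keep their address; the upper level sets the site type
    # (a fixed BLS station may be upgraded when its site turns ALS)
    fixed_by_site: dict = {}
    for sid in sorted(fixed_ids):
        st = cur.loc[sid]
        site = _site_for_municipality(st["municipality"], site_muni)
        if site is None:
            raise ValueError(f"fixed station {sid} has no open site in its municipality")
        used_sites.add(site)
        fixed_by_site.setdefault(site, []).append(sid)
    for site, sids in sorted(fixed_by_site.items(), key=lambda kv: str(kv[0])):
        site_is_als = site in als_sites
        ordered = sorted(sids, key=lambda s: (cur.loc[s, "type"] != "ALS", s))
        for rank, sid in enumerate(ordered):
            st = cur.loc[sid]
            if site_is_als:
                new_type = "ALS" if rank == 0 else st["type"]
            else:
                new_type = "BLS"
            placed_rows.append(
                {
                    "id": sid,
                    "node": st["node"],
                    "municipality": st["municipality"],
                    "type": new_type,
                    "moved_from": None,
                }
            )

    free_stations = cur[~cur["id"].isin(fixed_ids)]
    remaining_sites = [s for s in free_sites if s not in used_sites]
    site_type = {s: ("ALS" if s in als_sites else "BLS") for s in remaining_sites}

    # stations whose municipality still hosts an open free site stay put
    stay_ids, moved = [], []
    claimed: set = set()
    for sid in sorted(free_stations["id"]):
        st = cur.loc[sid]
        site = _site_for_municipality(
            st["municipality"], {s: site_muni[s] for s in remaining_sites if s not in claimed}
        )
        if site is not None:
            claimed.add(site)
            stay_ids.append((sid, site))
        else:
            moved.append(sid)
    new_sites = [s for s in remaining_sites if s not in claimed]

    for sid, site in stay_ids:
        st = cur.loc[sid]
        placed_rows.append(
            {
                "id": sid,
                "node": st["node"],
                "municipality": st["municipality"],
                "type": site_type[site],
                "moved_from": None,
            }
        )

    # match moved stations to new sites, same-type pairs first
    moved_df = cur.loc[moved]
    assign: list[tuple] = []
    pool = list(new_sites)
    for kind in ("ALS", "BLS"):
        origins = sorted(moved_df.loc[moved_df["type"] == kind, "id"])
        for sid in origins:
            pick = next((s for s in pool if site_type[s] == kind), None)
            if pick is None:
                continue
            pool.remove(pick)
            assign.append((sid, pick))
    leftovers = sorted(set(moved) - {sid for sid, _ in assign})
    for sid, s in zip(leftovers, pool):
        assign.append((sid, s))

    relocated_by_type = {"ALS": 0, "BLS": 0}
    switches = {"BLS_to_ALS": 0, "ALS_to_BLS": 0}
    for sid, site in assign:
        st = cur.loc[sid]
        new_type = site_type[site]
        relocated_by_type[new_type] += 1
        placed_rows.append(
            {
                "id": sid,
                "node": central_nodes[site_muni[site]],
                "municipality": site_muni[site],
                "type": new_type,
                "moved_from": st["municipality"],
            }
        )
    for r in placed_rows:
        old = cur.loc[r["id"], "type"]
        if old == "BLS" and r["type"] == "ALS":
            switches["BLS_to_ALS"] += 1
        elif old == "ALS" and r["type"] == "BLS":
            switches["ALS_to_BLS"] += 1

    plan = pd.DataFrame(placed_rows).sort_values("id").reset_index(drop=True)
    return DeploymentPlan(
        stations=plan,
        relocated_total=len(assign),
        relocated_by_type=relocated_by_type,
        type_switches=switches,
    )


def _site_for_municipality(municipality, site_muni: Mapping):
    matches = sorted((s for s, m in site_muni.items() if m == municipality), key=str)
    return matches[0] if matches else None


@dataclass
class StaticIndicators:
    """Congestion-free indicators computed from the travel-time matrix."""

    avg_travel_time_min: float
    avg_travel_time_als_min: float | None
    coverage_pct: float
    threshold_min: float


def static_indicators(
    solution: LocationSolution, instance: LocationInstance, threshold_min: float = 15.0
) -> StaticIndicators:
    """Average travel time = objective / total demand; threshold coverage.

    Coverage is the percentage of demand whose nearest open site is within
    ``threshold_min`` minutes (inclusive).
    """
    total = float(instance.b.sum())
    if total <= 0:
        raise ValueError("total demand is zero; averages undefined")
    cand = list(instance.candidates)
    open_idx = [cand.index(s) for s in solution.open_sites]
    nearest = instance.t[open_idx, :].min(axis=0)
    coverage = 100.0 * float(instance.b[nearest <= threshold_min].sum()) / total
    avg_up = None if solution.z_up is None else solution.z_up / total
    return StaticIndicators(
        avg_travel_time_min=solution.z_low / total,
        avg_travel_time_als_min=avg_up,
        coverage_pct=coverage,
        threshold_min=threshold_min,
    )
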