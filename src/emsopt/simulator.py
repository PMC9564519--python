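"""Agent-based discrete-event simulation of tiered (ALS/BLS) EMS operations.

Each station houses exactly one ambulance.  The dispatch policy mirrors the
tiered protocol: for a life-threatening (K) call the closest available
ambulance of any type responds, with the closest ALS dispatched concurrently
when the primary is BLS; urgent (N) calls get the closest BLS with a
probabilistic ALS backup requested at the start of on-scene care; non-urgent
(M) calls get the closest BLS unless it is too far, in which case an ALS may
respond instead.  Ambulances are dispatchable while idle at base or while
returning to base (en-route re-dispatch diverts them at the next road node).

Service on scene, the transport decision, hospital choice and the Erlang
drop-off follow configurable distributions; every event is logged with its
timestamp so that all performance indicators can be recomputed from the log.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .demand_model import CallDistribution, DemandZone, sample_call_stream
from .road_network import (
    RoadNetwork,
    Route,
    SpeedModel,
    divert_point,
    shortest_route,
)

MINUTES_PER_DAY = 1440.0

AMBULANCE_TYPES = ("ALS", "BLS")

#: ambulance states
IDLE, TO_SCENE, ON_SCENE, TO_HOSPITAL, AT_HOSPITAL, RETURNING = (
    "idle_at_base",
    "to_scene",
    "on_scene",
    "to_hospital",
    "at_hospital",
    "returning",
)

#: priority used for non-emergency (return-to-base) driving
RETURN_PRIORITY = "M"


class SimulationConfigError(Exception):
    """Inconsistent simulation configuration."""


class NoAdmissibleHospitalError(Exception):
    """No hospital admits the patient's age class / diagnosis."""


# ---------------------------------------------------------------------------
# entities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Station:
    id: str
    node: object
    kind: str  # "ALS" | "BLS"
    municipality: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in AMBULANCE_TYPES:
            raise ValueError(f"unknown station type {self.kind!r}")


@dataclass(frozen=True)
class Hospital:
    """Hospital with admission constraints and an Erlang drop-off time.

    ``admits`` is "adults", "children" or "both"; ``specializations`` is the
    set of diagnoses the hospital accepts (``None`` = all).  Drop-off time
    (hand-over plus vehicle cleaning/resupply) is Erlang with integer shape
    ``dropoff_shape`` and mean ``dropoff_mean_min``.
    """

    id: str
    node: object
    admits: str = "both"
    specializations: frozenset | None = None
    dropoff_mean_min: float = 25.0
    dropoff_shape: int = 3

    def __post_init__(self) -> None:
        if self.admits not in ("adults", "children", "both"):
            raise ValueError(f"unknown admits value {self.admits!r}")
        if self.dropoff_shape < 1:
            raise ValueError("Erlang shape must be >= 1")
        if self.dropoff_mean_min <= 0:
            raise ValueError("drop-off mean must be positive")

    def admissible(self, age_class: str, diagnosis: str) -> bool:
        if self.admits == "adults" and age_class == "child":
            return False
        if self.admits == "children" and age_class != "child":
            return False
        return self.specializations is None or diagnosis in self.specializations


@dataclass
class SimulationConfig:
    """Run-length, policy and service-time parameters of the simulator."""

    horizon_days: float = 91.0
    n_replications: int = 10
    p_support: float = 0.1  # probability an N-call crew requests ALS backup
    tau_m_min: float = 25.0  # "too far" threshold for M-calls
    cancel_support: bool = False  # recall an en-route support crew once the
    # primary has cleared the scene (off by default: the crew completes its trip)
    transport_prob: Mapping[str, float] = field(
        default_factory=lambda: {"BLS": 0.71, "ALS": 0.53}
    )
    on_scene_means: Mapping[str, Mapping[str, float]] | None = None  # diagnosis -> crew -> min
    on_scene_default: Mapping[str, float] = field(
        default_factory=lambda: {"BLS": 28.0, "ALS": 22.0}
    )
    on_scene_cv: float = 0.35  # lognormal coefficient of variation (0 = deterministic)

    def __post_init__(self) -> None:
        if self.horizon_days <= 0:
            raise SimulationConfigError("horizon must be positive")
        if self.n_replications < 1:
            raise SimulationConfigError("need at least one replication")
        for k, v in self.transport_prob.items():
            if not 0.0 <= v <= 1.0:
                raise SimulationConfigError(f"transport probability for {k} outside [0,1]")
        if not 0.0 <= self.p_support <= 1.0:
            raise SimulationConfigError("p_support outside [0,1]")
        if self.on_scene_cv < 0:
            raise SimulationConfigError("on-scene cv must be non-negative")

    def on_scene_mean(self, diagnosis: str, crew: str) -> float:
        if self.on_scene_means and diagnosis in self.on_scene_means:
            return float(self.on_scene_means[diagnosis][crew])
        return float(self.on_scene_default[crew])

    @property
    def horizon_min(self) -> float:
        return self.horizon_days * MINUTES_PER_DAY


@dataclass
class Call:
    id: int
    t_arrival: float
    node: object
    priority: str
    diagnosis: str
    age_class: str
    zone_id: str | None = None
    t_assign: float | None = None
    t_scene_arrival: float | None = None  # first arrival (primary or support)
    t_scene_depart: float | None = None
    t_hospital_arrival: float | None = None
    t_clear: float | None = None
    transported: bool | None = None
    hospital_id: str | None = None
    primary_amb: str | None = None
    support_amb: str | None = None
    arrivals: dict = field(default_factory=dict)  # ambulance id -> arrival time

    @property
    def response_time_min(self) -> float | None:
        if self.t_assign is None or self.t_scene_arrival is None:
            return None
        return self.t_scene_arrival - self.t_assign


class Ambulance:
    """One vehicle/crew state machine (one per station)."""

    def __init__(self, station: Station):
        self.id = station.id
        self.station = station
        self.kind = station.kind
        self.state = IDLE
        self.node = station.node  # last node reached (valid when not mid-route)
        self.route: Route | None = None
        self.call_id: int | None = None
        self.busy_start: float | None = None
        self.busy_min = 0.0
        self.distance_km = 0.0

    @property
    def dispatchable(self) -> bool:
        return self.state in (IDLE, RETURNING)


@dataclass
class ServicePlan:
    """Sampled service chain for one call: the outcome of ``serve_call``."""

    on_scene_min: float
    transported: bool
    hospital: Hospital | None
    dropoff_min: float | None


def serve_call(
    call: Call,
    crew_type: str,
    hospitals: Sequence[Hospital],
    network: RoadNetwork,
    speed_model: SpeedModel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ServicePlan:
    """Sample the service chain for a call attended by ``crew_type``.

    On-scene duration is lognormal with a (diagnosis, crew)-specific mean;
    transport to hospital is Bernoulli with the crew-type probability; when
    transported, the destination is the nearest admissible hospital by travel
    time (lowest id on ties) and the drop-off is Erlang-distributed there.
    """
    mean = config.on_scene_mean(call.diagnosis, crew_type)
    on_scene = _lognormal(rng, mean, config.on_scene_cv)
    transported = bool(rng.random() < config.transport_prob[crew_type])
    hospital = dropoff = None
    if transported:
        hospital = choose_hospital(call, hospitals, network, speed_model)
        dropoff = float(
            rng.gamma(hospital.dropoff_shape, hospital.dropoff_mean_min / hospital.dropoff_shape)
        )
    return ServicePlan(on_scene, transported, hospital, dropoff)


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv == 0.0:
        return float(mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def choose_hospital(
    call: Call,
    hospitals: Sequence[Hospital],
    network: RoadNetwork,
    speed_model: SpeedModel,
) -> Hospital:
    """Nearest admissible hospital by travel time; error when none admits."""
    best = None
    best_key = None
    for h in sorted(hospitals, key=lambda h: h.id):
        if not h.admissible(call.age_class, call.diagnosis):
            continue
        tt = shortest_route(
            network, speed_model, call.node, h.node, call.priority, 0.0
        ).total_time_min
        key = (tt, h.id)
        if best_key is None or key < best_key:
            best, best_key = h, key
    if best is None:
        raise NoAdmissibleHospitalError(
            f"no hospital admits diagnosis={call.diagnosis!r} age_class={call.age_class!r}"
        )
    return best


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class AmbulanceStats:
    id: str
    kind: str
    busy_min: float
    distance_km: float


@dataclass
class ReplicationResult:
    """Event log and end-of-run state of one simulation replication."""

    calls: list[Call]
    events: list[tuple]  # (time, type, call_id, ambulance_id, node)
    ambulances: list[AmbulanceStats]
    horizon_min: float
    n_censored: int

    @property
    def total_mileage_km(self) -> float:
        return float(sum(a.distance_km for a in self.ambulances))

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.events, columns=["time_min", "event", "call_id", "ambulance_id", "node"]
        )

    def events_csv(self) -> str:
        """Canonical text serialization (used for determinism checks)."""
        df = self.events_frame().copy()
        df["time_min"] = df["time_min"].map(lambda t: f"{t:.9f}")
        return df.to_csv(index=False)


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------


class SimulationEngine:
    """Event loop over one call stream; normally driven via run_replication."""

    def __init__(
        self,
        stations: Sequence[Station],
        hospitals: Sequence[Hospital],
        network: RoadNetwork,
        speed_model: SpeedModel,
        config: SimulationConfig,
        rng: np.random.Generator,
    ):
        if not stations:
            raise SimulationConfigError("deployment has no stations")
        self.network = network
        self.speed_model = speed_model
        self.hospitals = list(hospitals)
        self.config = config
        self.rng = rng
        self.fleet = [Ambulance(s) for s in sorted(stations, key=lambda s: s.id)]
        self.by_id = {a.id: a for a in self.fleet}
        self.calls: dict[int, Call] = {}
        self.queue: list[Call] = []
        self.events: list[tuple] = []
        self._heap: list = []
        self._seq = 0
        self._plans: dict[int, ServicePlan] = {}

    # -- event plumbing -----------------------------------------------------

    def _push(self, t: float, kind: str, payload: tuple) -> None:
        self._seq += 1
        heapq.heappush(self._heap, (t, self._seq, kind, payload))

    def _log(self, t: float, etype: str, call_id=None, amb_id=None, node=None) -> None:
        self.events.append((t, etype, call_id, amb_id, node))

    # -- travel helpers -----------------------------------------------------

    def _estimate(self, amb: Ambulance, dest, priority: str, now: float):
        """(total_minutes, plan) estimated travel from the current position.

        For a returning ambulance the estimate is the remaining time to the
        next node on its current route plus the shortest time onward from
        that node.
        """
        if amb.state == IDLE:
            route = shortest_route(
                self.network, self.speed_model, amb.node, dest, priority, now
            )
            return route.total_time_min, ("idle", route)
        node, t_node, dist = divert_point(amb.route, now)
        onward = shortest_route(
            self.network, self.speed_model, node, dest, priority, t_node
        )
        return (t_node - now) + onward.total_time_min, ("divert", node, t_node, dist, onward)

    def _start_leg(self, amb: Ambulance, plan, now: float) -> Route:
        """Commit the travel plan produced by ``_estimate``; returns the route."""
        if plan[0] == "idle":
            return plan[1]
        _, node, t_node, dist, onward = plan
        # finish the current edge to the divert node, book the driven distance
        driven = dist - amb.route.length_to_index(0)
        amb.distance_km += max(driven, 0.0)
        amb.node = node
        amb.route = None
        return onward

    # -- dispatch policy ----------------------------------------------------

    def _available(self, kinds: tuple[str, ...]) -> list[Ambulance]:
        return [a for a in self.fleet if a.dispatchable and a.kind in kinds]

    def _closest(self, cands: Sequence[Ambulance], dest, priority, now):
        best = None
        for amb in cands:
            tt, plan = self._estimate(amb, dest, priority, now)
            key = (tt, amb.id)
            if best is None or key < best[0]:
                best = (key, amb, tt, plan)
        if best is None:
            return None
        return best[1], best[2], best[3]

    def dispatch(self, call: Call, now: float) -> bool:
        """Apply the tiered dispatch policy; returns False to queue the call."""
        if call.priority == "K":
            pick = self._closest(self._available(("ALS", "BLS")), call.node, "K", now)
            if pick is None:
                return False
            amb, _, plan = pick
            self._assign(amb, call, plan, now, role="primary")
            if amb.kind == "BLS":
                sup = self._closest(self._available(("ALS",)), call.node, "K", now)
                if sup is not None:
                    self._assign(sup[0], call, sup[2], now, role="support")
            return True
        if call.priority == "N":
            pick = self._closest(self._available(("BLS",)), call.node, "N", now)
            if pick is None:
                return False
            self._assign(pick[0], call, pick[2], now, role="primary")
            return True
        # priority M: closest BLS, unless too far and a closer ALS exists
        pick = self._closest(self._available(("BLS",)), call.node, "M", now)
        if pick is None:
            return False
        amb, tt, plan = pick
        if tt > self.config.tau_m_min:
            alt = self._closest(self._available(("ALS",)), call.node, "M", now)
            if alt is not None and alt[1] < tt:
                amb, tt, plan = alt
        self._assign(amb, call, plan, now, role="primary")
        return True

    def _assign(self, amb: Ambulance, call: Call, plan, now: float, role: str) -> None:
        if amb.busy_start is None:
            amb.busy_start = now
        route = self._start_leg(amb, plan, now)
        amb.state = TO_SCENE
        amb.route = route
        amb.call_id = call.id
        if role == "primary":
            call.t_assign = now
            call.primary_amb = amb.id
        else:
            call.support_amb = amb.id
        self._log(now, f"dispatch_{role}", call.id, amb.id, call.node)
        self._push(route.arrival_time, "scene_arrival", (amb.id, call.id))

    # -- event handlers -----------------------------------------------------

    def on_arrival(self, call: Call, now: float) -> None:
        self.calls[call.id] = call
        self._log(now, "call_arrival", call.id, None, call.node)
        if not self.dispatch(call, now):
            self.queue.append(call)
            self._log(now, "queued", call.id, None, call.node)

    def on_scene_arrival(self, amb_id: str, call_id: int, now: float) -> None:
        amb = self.by_id[amb_id]
        if amb.call_id != call_id:
            return  # the leg was cancelled while the event was in flight
        call = self.calls[call_id]
        amb.distance_km += amb.route.total_length_km
        amb.node = call.node
        amb.route = None
        call.arrivals[amb_id] = now
        if call.t_scene_arrival is None:
            call.t_scene_arrival = now
        self._log(now, "scene_arrival", call_id, amb_id, call.node)
        if amb_id == call.primary_amb:
            amb.state = ON_SCENE
            plan = serve_call(
                call, amb.kind, self.hospitals, self.network, self.speed_model,
                self.config, self.rng,
            )
            call.transported = plan.transported
            if plan.hospital is not None:
                call.hospital_id = plan.hospital.id
            self._plans[call_id] = plan
            if call.priority == "N" and self.rng.random() < self.config.p_support:
                sup = self._closest(self._available(("ALS",)), call.node, "N", now)
                if sup is not None:
                    self._assign(sup[0], call, sup[2], now, role="support")
            self._push(now + plan.on_scene_min, "scene_depart", (amb_id, call_id))
        else:  # support crew
            if call.t_scene_depart is not None:
                self._send_home(amb, call.node, now)
            else:
                amb.state = ON_SCENE

    def on_scene_depart(self, amb_id: str, call_id: int, now: float) -> None:
        amb = self.by_id[amb_id]
        call = self.calls[call_id]
        call.t_scene_depart = now
        plan: ServicePlan = self._plans.pop(call_id)
        self._log(now, "scene_depart", call_id, amb_id, call.node)
        # release the support crew, if it is on scene (or recall it en route
        # when the cancel rule is active)
        if call.support_amb is not None:
            sup = self.by_id[call.support_amb]
            if sup.state == ON_SCENE and sup.call_id == call_id:
                self._send_home(sup, call.node, now)
            elif (
                self.config.cancel_support
                and sup.state == TO_SCENE
                and sup.call_id == call_id
            ):
                node, t_node, dist = divert_point(sup.route, now)
                sup.distance_km += dist
                sup.route = None
                sup.node = node
                sup.call_id = None
                self._log(now, "support_cancelled", call_id, sup.id, node)
                self._push(t_node, "divert_arrival", (sup.id,))
        if plan.transported:
            route = shortest_route(
                self.network, self.speed_model, call.node, plan.hospital.node,
                call.priority, now,
            )
            amb.state = TO_HOSPITAL
            amb.route = route
            self._push(
                route.arrival_time, "hospital_arrival", (amb_id, call_id, plan.dropoff_min)
            )
        else:
            call.t_clear = now
            self._send_home(amb, call.node, now)

    def on_hospital_arrival(self, amb_id: str, call_id: int, dropoff: float, now: float) -> None:
        amb = self.by_id[amb_id]
        call = self.calls[call_id]
        amb.distance_km += amb.route.total_length_km
        amb.node = amb.route.nodes[-1]
        amb.route = None
        amb.state = AT_HOSPITAL
        call.t_hospital_arrival = now
        self._log(now, "hospital_arrival", call_id, amb_id, amb.node)
        self._push(now + dropoff, "dropoff_done", (amb_id, call_id))

    def on_dropoff_done(self, amb_id: str, call_id: int, now: float) -> None:
        amb = self.by_id[amb_id]
        call = self.calls[call_id]
        call.t_clear = now
        self._log(now, "dropoff_done", call_id, amb_id, amb.node)
        self._send_home(amb, amb.node, now)

    def _send_home(self, amb: Ambulance, from_node, now: float) -> None:
        """Release an ambulance towards its base; it becomes dispatchable."""
        amb.call_id = None
        if from_node == amb.station.node:
            amb.state = IDLE
            amb.node = amb.station.node
            amb.route = None
            if amb.busy_start is not None:
                amb.busy_min += now - amb.busy_start
                amb.busy_start = None
            self._log(now, "at_base", None, amb.id, amb.station.node)
        else:
            route = shortest_route(
                self.network, self.speed_model, from_node, amb.station.node,
                RETURN_PRIORITY, now,
            )
            amb.state = RETURNING
            amb.route = route
            self._log(now, "returning", None, amb.id, from_node)
            self._push(route.arrival_time, "base_arrival", (amb.id,))
        self._check_queue(now)

    def on_base_arrival(self, amb_id: str, now: float) -> None:
        amb = self.by_id[amb_id]
        if amb.state != RETURNING:
            return  # re-dispatched en route; the stale event is void
        amb.distance_km += amb.route.total_length_km
        amb.node = amb.station.node
        amb.route = None
        amb.state = IDLE
        if amb.busy_start is not None:
            amb.busy_min += now - amb.busy_start
            amb.busy_start = None
        self._log(now, "at_base", None, amb_id, amb.station.node)

    def _check_queue(self, now: float) -> None:
        """Serve queued calls in strict priority (K>N>M), FIFO within class."""
        progressed = True
        while progressed and self.queue:
            progressed = False
            order = sorted(
                range(len(self.queue)),
                key=lambda k: ({"K": 0, "N": 1, "M": 2}[self.queue[k].priority], k),
            )
            for k in order:
                call = self.queue[k]
                if self.dispatch(call, now):
                    self.queue.pop(k)
                    progressed = True
                    break

    # -- main loop ----------------------------------------------------------

    def run(self, stream: pd.DataFrame) -> ReplicationResult:
        for i, row in enumerate(stream.itertuples(index=False)):
            call = Call(
                id=i,
                t_arrival=float(row.time_min),
                node=row.node,
                priority=row.priority,
                diagnosis=row.diagnosis,
                age_class=row.age_class,
                zone_id=getattr(row, "zone_id", None),
            )
            self._push(call.t_arrival, "call_arrival", (call,))
        handlers = {
            "call_arrival": lambda t, p: self.on_arrival(p[0], t),
            "scene_arrival": lambda t, p: self.on_scene_arrival(p[0], p[1], t),
            "scene_depart": lambda t, p: self.on_scene_depart(p[0], p[1], t),
            "hospital_arrival": lambda t, p: self.on_hospital_arrival(p[0], p[1], p[2], t),
            "dropoff_done": lambda t, p: self.on_dropoff_done(p[0], p[1], t),
            "base_arrival": lambda t, p: self.on_base_arrival(p[0], t),
            "divert_arrival": lambda t, p: self._send_home(
                self.by_id[p[0]], self.by_id[p[0]].node, t
            ),
        }
        while self._heap:
            t, _, kind, payload = heapq.heappop(self._heap)
            handlers[kind](t, payload)
        # any call still queued when the event list is exhausted is censored
        n_censored = len(self.queue)
        for call in self.queue:
            self._log(call.t_arrival, "censored", call.id, None, call.node)
        stats = [
            AmbulanceStats(a.id, a.kind, a.busy_min, a.distance_km) for a in self.fleet
        ]
        return ReplicationResult(
            calls=[self.calls[k] for k in sorted(self.calls)],
            events=self.events,
            ambulances=stats,
            horizon_min=self.config.horizon_min,
            n_censored=n_censored,
        )


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


@dataclass
class EmsSystem:
    """Static world a deployment is simulated in."""

    network: RoadNetwork
    speed_model: SpeedModel
    hospitals: Sequence[Hospital]
    zones: Sequence[DemandZone] = ()


def run_replication(
    system: EmsSystem,
    stations: Sequence[Station],
    demand: pd.DataFrame | CallDistribution,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
) -> ReplicationResult:
    """One simulation replication, fully reproducible from ``seed``.

    ``demand`` is either a pre-sampled call stream (a calls DataFrame) or a
    :class:`CallDistribution`, in which case the stream is drawn over the
    configured horizon using the system's zones.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    demand_ss, service_ss = ss.spawn(2)
    if isinstance(demand, CallDistribution):
        stream = sample_call_stream(
            demand, system.zones, config.horizon_days, np.random.default_rng(demand_ss)
        )
    else:
        stream = demand.sort_values("time_min", kind="stable").reset_index(drop=True)
        stream = stream[stream["time_min"] <= config.horizon_min]
    engine = SimulationEngine(
        stations, system.hospitals, system.network, system.speed_model, config,
        np.random.default_rng(service_ss),
    )
    return engine.run(stream)


def run_replications(
    system: EmsSystem,
    stations: Sequence[Station],
    demand: pd.DataFrame | CallDistribution,
    config: SimulationConfig,
    master_seed: int = 0,
    n: int | None = None,
) -> list[ReplicationResult]:
    """Independent replications with seeds derived from ``master_seed``."""
    n = config.n_replications if n is None else n
    seeds = np.random.SeedSequence(master_seed).spawn(n)
    return [run_replication(system, stations, demand, config, s) for s in seeds]


# ---------------------------------------------------------------------------
# deployment CSV dialect
# ---------------------------------------------------------------------------


def write_deployment_csv(stations: Sequence[Station], path) -> None:
    pd.DataFrame(
        [
            {"id": s.id, "node": s.node, "type": s.kind, "municipality": s.municipality}
            for s in stations
        ]
    ).to_csv(path, index=False)


def read_deployment_csv(path, node_type=int) -> list[Station]:
    df = pd.read_csv(path)
    return [
        Station(
            id=str(r.id),
            node=node_type(r.node),
            kind=r.type,
            municipality=None if pd.isna(r.municipality) else str(r.municipality),
        )
        for r in df.itertuples(index=False)
    ]
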