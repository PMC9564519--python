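import numpy as np
import pytest

from emsopt.road_network import SpeedModel
from emsopt.simulator import (
    Call,
    EmsSystem,
    Hospital,
    NoAdmissibleHospitalError,
    SimulationConfig,
    SimulationEngine,
    Station,
    choose_hospital,
    run_replication,
    run_replications,
    serve_call,
)

from conftest import (
    FakeRng,
    call_stream,
    deterministic_sim_config,
    make_network,
    static_speeds,
)


@pytest.fixture
def speeds():
    return SpeedModel(
        base={"highway": (90.0, 90.0), "main": (60.0, 60.0), "local": (40.0, 40.0)}
    )


def engine_for(line_world, speeds, config, rng):
    network, stations, hospitals = line_world
    return SimulationEngine(stations, hospitals, network, speeds, config, rng)


class TestHandTracedMicroScenario:
    """One station, fixed durations: every timestamp follows by arithmetic.

    Station at node 0, scene at node 1 (7 km of 60 km/h road -> 7 min),
    hospital at node 2 (10 km -> 10 min), on-scene exactly 20 min, drop-off
    at its 15-min mean, return legs at priority-M speed (54 km/h).
    """

    def test_full_transport_chain_timestamps(self, line_world, speeds):
        config = deterministic_sim_config(transport_prob={"BLS": 1.0, "ALS": 1.0})
        eng = engine_for(line_world, speeds, config, FakeRng([0.0]))
        stream = call_stream([(600.0, "M0", 1, "K", "chest_pain", "adult")])
        log = eng.run(stream)
        c = log.calls[0]
        assert c.t_assign == 600.0
        assert c.t_scene_arrival == pytest.approx(607.0)
        assert c.response_time_min == pytest.approx(7.0)
        assert c.t_scene_depart == pytest.approx(627.0)
        assert c.t_hospital_arrival == pytest.approx(637.0)
        # clear = arrival + travel 7 + scene 20 + to-hospital 10 + drop-off 15
        assert c.t_clear == pytest.approx(652.0)
        assert c.transported and c.hospital_id == "H0"
        amb = log.ambulances[0]
        # mileage: 7 out + 10 to hospital + 17 home
        assert amb.distance_km == pytest.approx(34.0)
        # busy until back at base: return 17 km at 54 km/h
        ret = 17.0 / 54.0 * 60.0
        assert amb.busy_min == pytest.approx(652.0 - 600.0 + ret)

    def test_no_transport_skips_hospital_legs(self, line_world, speeds):
        config = deterministic_sim_config()  # transport probability zero
        eng = engine_for(line_world, speeds, config, FakeRng([0.5]))
        log = eng.run(call_stream([(600.0, "M0", 1, "N", "fall", "adult")]))
        c = log.calls[0]
        assert c.transported is False
        assert c.t_hospital_arrival is None
        assert c.t_clear == pytest.approx(627.0)
        assert not any(e[1] == "hospital_arrival" for e in log.events)

    def test_second_call_assigned_at_release_time(self, line_world, speeds):
        """With one ambulance, an overlapping call waits until the crew is
        released (starts returning), then is dispatched at that instant."""
        config = deterministic_sim_config()
        eng = engine_for(line_world, speeds, config, FakeRng([0.5]))
        stream = call_stream(
            [
                (600.0, "M0", 1, "N", "fall", "adult"),
                (601.0, "M0", 1, "N", "fall", "adult"),
            ]
        )
        log = eng.run(stream)
        first, second = log.calls
        release = first.t_clear  # scene node != base, crew released there
        assert second.t_assign == pytest.approx(release)
        assert second.t_scene_arrival == pytest.approx(release)  # already on scene node
        assert log.n_censored == 0


class TestDispatchPolicy:
    def two_station_world(self):
        # BLS at node 0 (close), ALS at node 2 (far); scene at node 1
        network = make_network(
            [(0, 0, 0, False), (1, 5, 0, False), (2, 15, 0, False)],
            [(0, 1, 5.0, "main"), (1, 2, 10.0, "main")],
        )
        stations = [
            Station(id="B1", node=0, kind="BLS"),
            Station(id="A1", node=2, kind="ALS"),
        ]
        hospitals = [Hospital(id="H0", node=2)]
        return network, stations, hospitals

    def test_k_call_with_bls_primary_gets_als_support(self, speeds):
        eng = engine_for(
            self.two_station_world(), speeds, deterministic_sim_config(), FakeRng([0.5])
        )
        log = eng.run(call_stream([(600.0, "Z", 1, "K", "cardiac_arrest", "adult")]))
        c = log.calls[0]
        assert c.primary_amb == "B1"
        assert c.support_amb == "A1"
        assert c.response_time_min == pytest.approx(5.0)  # first arrival counts
        assert len(c.arrivals) == 2

    def test_k_call_with_als_primary_no_dual(self, speeds):
        network, stations, hospitals = self.two_station_world()
        stations = [Station(id="A1", node=0, kind="ALS"), Station(id="B1", node=2, kind="BLS")]
        eng = SimulationEngine(
            stations, hospitals, network, speeds, deterministic_sim_config(), FakeRng([0.5])
        )
        log = eng.run(call_stream([(600.0, "Z", 1, "K", "stroke", "adult")]))
        assert log.calls[0].primary_amb == "A1"
        assert log.calls[0].support_amb is None

    def test_n_call_prefers_bls_even_if_farther(self, speeds):
        network, _, hospitals = self.two_station_world()
        stations = [Station(id="A1", node=0, kind="ALS"), Station(id="B1", node=2, kind="BLS")]
        eng = SimulationEngine(
            stations, hospitals, network, speeds, deterministic_sim_config(), FakeRng([0.5])
        )
        log = eng.run(call_stream([(600.0, "Z", 1, "N", "fall", "adult")]))
        assert log.calls[0].primary_amb == "B1"

    def test_m_call_far_bls_replaced_by_closer_als(self, speeds):
        network, _, hospitals = self.two_station_world()
        stations = [Station(id="A1", node=0, kind="ALS"), Station(id="B1", node=2, kind="BLS")]
        cfg = deterministic_sim_config(tau_m_min=5.0)  # BLS is ~11 min away
        eng = SimulationEngine(stations, hospitals, network, speeds, cfg, FakeRng([0.5]))
        log = eng.run(call_stream([(600.0, "Z", 1, "M", "fall", "adult")]))
        assert log.calls[0].primary_amb == "A1"

    def test_support_completes_trip_by_default(self, speeds):
        """The dual-dispatched ALS reaches the scene even if the primary has
        already cleared it, then returns home."""
        network, stations, hospitals = self.two_station_world()
        cfg = deterministic_sim_config(on_scene_default={"BLS": 2.0, "ALS": 2.0})
        eng = SimulationEngine(stations, hospitals, network, speeds, cfg, FakeRng([0.5]))
        log = eng.run(call_stream([(600.0, "Z", 1, "K", "stroke", "adult")]))
        c = log.calls[0]
        assert c.support_amb == "A1"
        assert "A1" in c.arrivals  # primary cleared at 607, ALS arrives 610

    def test_support_recalled_when_cancel_rule_active(self, speeds):
        network, stations, hospitals = self.two_station_world()
        cfg = deterministic_sim_config(
            on_scene_default={"BLS": 2.0, "ALS": 2.0}, cancel_support=True
        )
        eng = SimulationEngine(stations, hospitals, network, speeds, cfg, FakeRng([0.5]))
        log = eng.run(call_stream([(600.0, "Z", 1, "K", "stroke", "adult")]))
        c = log.calls[0]
        assert c.support_amb == "A1"
        assert "A1" not in c.arrivals
        assert any(e[1] == "support_cancelled" for e in log.events)
        # the recalled crew still ends idle at its own base
        assert all(a.busy_min > 0 for a in log.ambulances)

    def test_all_busy_queues_in_priority_order(self, speeds):
        network, stations, hospitals = self.two_station_world()
        stations = stations[:1]  # single BLS
        cfg = deterministic_sim_config()
        eng = SimulationEngine(stations, hospitals, network, speeds, cfg, FakeRng([0.5]))
        stream = call_stream(
            [
                (600.0, "Z", 1, "N", "fall", "adult"),
                (601.0, "Z", 1, "M", "fall", "adult"),  # queued
                (602.0, "Z", 1, "K", "stroke", "adult"),  # queued, jumps the M call
            ]
        )
        log = eng.run(stream)
        k_call = log.calls[2]
        m_call = log.calls[1]
        assert k_call.t_assign < m_call.t_assign

    def test_en_route_redispatch_starts_from_next_node(self, speeds):
        """An ambulance returning to base diverts at the next reachable node."""
        network, _, hospitals = self.two_station_world()
        stations = [Station(id="B1", node=0, kind="BLS")]
        cfg = deterministic_sim_config()
        eng = SimulationEngine(stations, hospitals, network, speeds, cfg, FakeRng([0.5]))
        # first call: out 5 min, scene 20 min, released at 625 from node 1;
        # the second call arrives while the crew drives home (5 km at 54 km/h)
        stream = call_stream(
            [
                (600.0, "Z", 1, "N", "fall", "adult"),
                (629.0, "Z", 1, "N", "fall", "adult"),
            ]
        )
        log = eng.run(stream)
        second = log.calls[1]
        assert second.t_assign == pytest.approx(629.0)
        # the crew finishes the 1-0 edge to node 0, then drives back 5 km
        t_reach_base = 625.0 + 5.0 / 54.0 * 60.0
        expected_arrival = t_reach_base + 5.0  # 5 km at 60 km/h, priority N
        assert second.t_scene_arrival == pytest.approx(expected_arrival)


class TestServeCall:
    def world(self):
        network = make_network(
            [(0, 0, 0, False), (1, 5, 0, False), (2, 9, 0, False)],
            [(0, 1, 5.0, "main"), (1, 2, 4.0, "main")],
        )
        hospitals = [
            Hospital(id="HA", node=1, admits="adults", dropoff_mean_min=20.0),
            Hospital(id="HC", node=2, admits="children", dropoff_mean_min=20.0),
        ]
        return network, hospitals

    def make_call(self, age="adult", diagnosis="fall"):
        return Call(id=0, t_arrival=0.0, node=0, priority="N",
                    diagnosis=diagnosis, age_class=age)

    def test_transport_fraction_recovers_defaults(self, speeds):
        """10^4 sampled services hit the 0.71 / 0.53 transport shares."""
        network, hospitals = self.world()
        config = SimulationConfig(horizon_days=1)
        rng = np.random.default_rng(2024)
        for kind, p in (("BLS", 0.71), ("ALS", 0.53)):
            n = 10_000
            hits = sum(
                serve_call(self.make_call(), kind, hospitals, network, speeds,
                           config, rng).transported
                for _ in range(n)
            )
            se = np.sqrt(p * (1 - p) / n)
            assert abs(hits / n - p) <= 3 * se

    def test_on_scene_mean_is_higher_for_bls(self, speeds):
        network, hospitals = self.world()
        config = SimulationConfig(horizon_days=1)
        rng = np.random.default_rng(5)
        bls = [serve_call(self.make_call(), "BLS", hospitals, network, speeds,
                          config, rng).on_scene_min for _ in range(2000)]
        als = [serve_call(self.make_call(), "ALS", hospitals, network, speeds,
                          config, rng).on_scene_min for _ in range(2000)]
        assert 20.0 < np.mean(bls) < 32.0
        assert np.mean(als) < np.mean(bls)

    def test_child_goes_to_childrens_hospital(self, speeds):
        network, hospitals = self.world()
        c = self.make_call(age="child")
        assert choose_hospital(c, hospitals, network, speeds).id == "HC"

    def test_no_admissible_hospital_raises(self, speeds):
        network, _ = self.world()
        only_children = [Hospital(id="HC", node=2, admits="children")]
        with pytest.raises(NoAdmissibleHospitalError, match="fall"):
            choose_hospital(self.make_call(age="adult"), only_children, network, speeds)

    def test_dropoff_mean_matches_erlang_parameters(self, speeds):
        network, hospitals = self.world()
        config = SimulationConfig(horizon_days=1, transport_prob={"BLS": 1.0, "ALS": 1.0})
        rng = np.random.default_rng(6)
        drops = [
            serve_call(self.make_call(), "BLS", hospitals, network, speeds,
                       config, rng).dropoff_min
            for _ in range(4000)
        ]
        assert np.mean(drops) == pytest.approx(20.0, rel=0.05)


class TestReplications:
    def system(self, line_world):
        network, stations, hospitals = line_world
        from emsopt.demand_model import CallDistribution, DemandZone

        zones = [
            DemandZone(id="M0", level="municipality", anchor_node=1,
                       population=1000.0, nodes=(0, 1, 2)),
        ]
        dist = CallDistribution(
            hourly_rates=np.full(24, 0.25),
            priority_mix={"K": 0.2, "N": 0.5, "M": 0.3},
            diagnosis_probs={"chest_pain": 0.3, "fall": 0.7},
            age_probs={"adult": 1.0},
        )
        speeds = SpeedModel()
        return EmsSystem(network, speeds, hospitals, zones), stations, dist

    def test_zero_rate_demand_empty_log(self, line_world):
        system, stations, dist = self.system(line_world)
        from emsopt.demand_model import CallDistribution

        silent = CallDistribution(
            hourly_rates=np.zeros(24), priority_mix=dist.priority_mix,
            diagnosis_probs=dist.diagnosis_probs, age_probs=dist.age_probs,
        )
        cfg = SimulationConfig(horizon_days=2, n_replications=1)
        log = run_replication(system, stations, silent, cfg, seed=3)
        assert log.calls == [] and log.total_mileage_km == 0.0

    def test_same_seed_byte_identical_logs(self, line_world):
        system, stations, dist = self.system(line_world)
        cfg = SimulationConfig(horizon_days=3, n_replications=1)
        a = run_replication(system, stations, dist, cfg, seed=11)
        b = run_replication(system, stations, dist, cfg, seed=11)
        assert a.events_csv() == b.events_csv()

    def test_different_seeds_differ(self, line_world):
        system, stations, dist = self.system(line_world)
        cfg = SimulationConfig(horizon_days=3, n_replications=1)
        a = run_replication(system, stations, dist, cfg, seed=11)
        b = run_replication(system, stations, dist, cfg, seed=12)
        assert a.events_csv() != b.events_csv()

    def test_replication_set_reproducible(self, line_world):
        system, stations, dist = self.system(line_world)
        cfg = SimulationConfig(horizon_days=2, n_replications=3)
        logs1 = run_replications(system, stations, dist, cfg, master_seed=7)
        logs2 = run_replications(system, stations, dist, cfg, master_seed=7)
        assert len(logs1) == 3
        for x, y in zip(logs1, logs2):
            assert x.events_csv() == y.events_csv()
        # replications are mutually independent streams
        assert logs1[0].events_csv() != logs1[1].events_csv()

    def test_conservation_served_plus_censored(self, line_world):
        system, stations, dist = self.system(line_world)
        cfg = SimulationConfig(horizon_days=5, n_replications=1)
        log = run_replication(system, stations, dist, cfg, seed=19)
        served = sum(1 for c in log.calls if c.t_scene_arrival is not None)
        assert served + log.n_censored == len(log.calls)
        for c in log.calls:
            if c.t_scene_arrival is not None:
                assert c.primary_amb is not None
                assert c.response_time_min >= 0

    def test_no_ambulance_double_booked(self, line_world):
        """While serving one call an ambulance is never dispatched to another."""
        system, stations, dist = self.system(line_world)
        cfg = SimulationConfig(horizon_days=5, n_replications=1)
        log = run_replication(system, stations, dist, cfg, seed=23)
        intervals = []
        for c in log.calls:
            if c.primary_amb and c.t_clear is not None:
                intervals.append((c.t_assign, c.t_clear, c.primary_amb))
        intervals.sort()
        for (a0, a1, amb_a), (b0, b1, amb_b) in zip(intervals, intervals[1:]):
            if amb_a == amb_b:
                assert b0 >= a1 - 1e-9

    def test_workload_identity_single_node(self, speeds):
        """All travel collapsed to one node: total busy time = calls x 30 min."""
        network = make_network([(0, 0, 0, False)], [])
        stations = [Station(id="B1", node=0, kind="BLS"), Station(id="B2", node=0, kind="BLS")]
        hospitals = [Hospital(id="H", node=0)]
        from emsopt.demand_model import CallDistribution, DemandZone

        zones = [DemandZone(id="Z", level="municipality", anchor_node=0, population=10.0)]
        dist = CallDistribution(
            hourly_rates=np.full(24, 1.0), priority_mix={"K": 0.0, "N": 1.0, "M": 0.0},
            diagnosis_probs={"fall": 1.0}, age_probs={"adult": 1.0},
        )
        system = EmsSystem(network, speeds, hospitals, zones)
        cfg = SimulationConfig(
            horizon_days=4, n_replications=1, p_support=0.0,
            transport_prob={"BLS": 0.0, "ALS": 0.0},
            on_scene_default={"BLS": 30.0, "ALS": 30.0}, on_scene_cv=0.0,
        )
        log = run_replication(system, stations, dist, cfg, seed=31)
        total_busy = sum(a.busy_min for a in log.ambulances)
        assert total_busy == pytest.approx(30.0 * len(log.calls))
        assert log.total_mileage_km == 0.0
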