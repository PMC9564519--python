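# emsopt

Redesigning the station network of a tiered emergency medical service (EMS)
in a mixed urban-rural region: where should ambulance stations sit, which of
them should house an advanced-life-support (ALS) crew rather than a
basic-life-support (BLS) crew, and what does a proposed redesign do to
response times once real operations — busy crews, hospital transports,
re-dispatching en route — are accounted for?

The package is aimed at EMS planners and operations researchers.  It couples
two classical tools:

1. **A hierarchical pq-median location model.**  With candidate sites *I*,
   demand points *J*, shortest travel times *t<sub>ij</sub>* and demand
   weights *b<sub>j</sub>*, the lower level opens *p* station sites

   minimize Σ<sub>i</sub> Σ<sub>j</sub> t<sub>ij</sub> b<sub>j</sub> x<sub>ij</sub>
   subject to each zone assigned to exactly one open site, Σ y<sub>i</sub> = p,

   and the upper level then picks *q* of the opened sites for ALS crews
   (u<sub>i</sub> ≤ y<sub>i</sub>, Σ u<sub>i</sub> = q), minimizing the same
   weighted travel-time objective for the ALS tier.  The hierarchy is
   non-coherent: BLS and ALS catchment areas need not nest.  Pre-processing
   fixes stations in high-demand towns (capacity rule and small-town rule)
   and a relocation budget *r* bounds how many free stations may move to new
   municipalities.  Both levels are solved to proven optimality with HiGHS
   (`scipy.optimize.milp`).

2. **An agent-based discrete-event simulator** of tiered operations: calls
   arrive by a non-homogeneous Poisson process with an hour-of-day profile,
   are placed on the road network proportionally to population, and are
   served under the tiered dispatch policy (closest unit of any type for
   life-threatening K calls with concurrent ALS dual dispatch when the
   primary is BLS; closest BLS for urgent N calls with probabilistic ALS
   backup; closest BLS for non-urgent M calls unless too far).  Travel
   speeds depend on road category, built-up areas, call priority and rush
   hours; crews can be re-dispatched while returning to base.  On-scene
   times, transport-to-hospital decisions (defaults 71% for BLS, 53% for
   ALS) and Erlang hospital drop-offs are all configurable distributions.

Because the underlying national datasets of such studies are generally not
public, the package ships a synthetic-country generator
(`emsopt.synthetic_data`) that reproduces the statistical structure the
method assumes — heavy-tailed municipality populations, a bimodal daily call
profile, 250 m town grids — so the whole two-stage pipeline is exercisable
and testable end to end from a single seed.

## Worked example

```python
from emsopt.cli import PipelineConfig, run_pipeline, scenario_table
from emsopt.simulator import SimulationConfig

cfg = PipelineConfig(
    history_days=60.0,
    sim=SimulationConfig(horizon_days=7.0, n_replications=3),
    seed=1,
)
result = run_pipeline(cfg)
print(scenario_table(result.scenarios)[
    ["scenario", "budget", "relocated", "avg_travel_time_min", "coverage_15min_pct"]
].to_string(index=False))
for label in ("current", "40pct"):
    rep = result.reports[label]
    print(label, "mean RT %.2f min" % rep.values["mean_rt_overall"][0])
```

prints (tiny preset, seed 1):

```
    scenario  budget  relocated  avg_travel_time_min  coverage_15min_pct
       10pct       1          1             7.040220           72.691682
       20pct       2          2             2.140730           89.835237
       30pct       2          2             2.140730           89.835237
       40pct       3          3             1.814343           91.807505
       50pct       4          3             1.814343           91.807505
unrestricted       7          3             1.814343           91.807505
current mean RT 18.90 min
40pct mean RT 13.06 min
```

Reading this: as the relocation budget grows from 10% to the unrestricted
scenario, the static (congestion-free) average travel time from the nearest
station falls monotonically and the share of demand within 15 minutes rises;
the simulation then confirms that the 40%-relocation deployment cuts the
realistic mean response time from 18.9 to 13.1 minutes on this synthetic
country.  The same pipeline is available from the shell:

```sh
emsopt pipeline --preset tiny --seed 1 --out runs/demo
emsopt synth --preset tiny --seed 0 --days 30 --out runs/inputs
emsopt simulate --seed 2 --horizon-days 3 --replications 2 --out runs/a.json
emsopt compare --a runs/a.json --b runs/a.json
```

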