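# Methods

## Problem and model

The package redesigns the station network of a two-tier EMS system with a
fixed fleet: `p` stations in total, `q` of them housing advanced-life-support
(ALS) crews, the rest basic-life-support (BLS).  Station placement is a
hierarchical pq-median problem: the lower level chooses the `p` sites
minimizing the demand-weighted total travel time to the nearest open site,
and the upper level chooses `q` of those sites for ALS crews with the same
objective restricted to the ALS tier.  The hierarchy is *non-coherent*: a
zone's BLS station and ALS station need not coincide or nest.  The model is
uncapacitated — every zone is served by its nearest open site — so dividing
the optimal objective by total demand gives the average travel time, and the
share of demand whose nearest open site is within a threshold gives the
theoretical coverage.

Demand is represented at two spatial levels: one zone per municipality
nationwide (anchored at its central road node), and 250 m square grid cells
inside towns selected for a second, within-town optimization stage.  Zone
weights are counts of historical life-threatening (K) and urgent (N) calls;
non-urgent (M) calls are simulated but carry no weight in the location
model.  Demand elasticity is not modelled.

## Exactness and the MIP backend

Both levels are solved as mixed-integer programs with HiGHS through
`scipy.optimize.milp`.  Site variables are binary; assignment variables are
left continuous because with disaggregated linking constraints
(x<sub>ij</sub> ≤ y<sub>i</sub>) the assignment subproblem is a plain
minimum once the sites are fixed, so an optimal basis is integral.  After
each solve the assignment is canonicalised to nearest-open-site with a
lowest-id tie-break and its cost is checked against the solver objective at
1e-6 relative tolerance; any disagreement raises rather than returning an
incumbent.  The test suite verifies both levels against exhaustive subset
enumeration on hundreds of random instances (|I| ≤ 12, p ≤ 4, q ≤ 2), with
and without fixed sites and relocation budgets.

## Fixing rules and the relocation budget

Because the uncapacitated model would concentrate whole metropolitan areas
on one site, stations are fixed before optimization.  The station capacity is
C = total population / station count.  Capacity rule: a town with k stations
and population P keeps all k when P > kC; otherwise ⌊P/C⌋ stations are fixed
and the town's demand weight is scaled by 1 − ⌊P/C⌋·C/P (floor rather than
ceiling — a ceiling would re-fix every near-capacity town and empty the
rule of content).  Small-town rule: a town with exactly two stations and
P < C keeps one (demand unscaled).  Within a town, ALS stations are fixed
first, then ascending id: this keeps the scarcer tier anchored where backup
matters most and is deterministic.  Fixed ALS stations keep their type; fixed
BLS stations may still be upgraded by the upper level.

The relocation budget r (a fraction of the total station count, rounded to
the nearest integer, or "unrestricted" = all free stations) enters the MIP
as Σ<sub>i ∈ current free sites</sub> y<sub>i</sub> ≥ p_free − r, with
`current free sites` the *set* of municipalities hosting free stations.  Two
free stations sharing one municipality cannot both be represented by a
binary site variable; the second and further such stations stay resident at
their current address and are treated like fixed stations (with switchable
type).  In the synthetic worlds multiple stations per municipality occur
only in towns, where the fixing rules usually absorb them anyway.

At most one station is opened per node.  Post-processing keeps non-relocated
stations at their current addresses, places relocated ones at the target
municipality's central node, and counts a station as relocated iff its
municipality changed; when matching moved stations to new sites, same-type
pairs are matched first so that type-switch counts are not inflated by the
arbitrary matching.

## Travel times and routing

Edges carry a length and a road category (highway / main / local); speed
depends additionally on whether the edge lies in a built-up area (both
endpoints built-up), the call priority, and rush hours (06:30–09:00 and
15:00–18:00).  The shipped default table — highway 90/72, main 60/48, local
40/32 km/h off-peak/rush, ×0.8 built-up, ×0.9 for priority M — is a
documented, fully overridable placeholder (YAML); the field's real speed
estimates are operator-specific.  Return-to-base legs drive at priority-M
speed as a non-emergency proxy.

Routing minimises travel time with each edge's speed frozen at its entry
time.  The time-dependent Dijkstra is exact under the FIFO property; the
frozen-entry model violates FIFO only in the minutes before a rush window
ends, where a route can be marginally suboptimal.  This is accepted as
standard behaviour for discrete-event road models.  The travel-time matrix
that feeds the MIP uses a single static context — priority K, off-peak, no
built-up penalty — because a time-varying matrix would make the location
model ill-defined; the context is an argument, not a constant.

Re-dispatch of a returning ambulance starts from the next node on its
current route: the crew finishes the edge it is on, then follows a fresh
shortest route.  Mileage is booked per completed leg, with the partial
return leg booked up to the diversion node.

## Simulator

One ambulance per station.  Dispatch policy: K — closest available unit of
any type, plus the closest available ALS concurrently when the primary is
BLS; N — closest available BLS, with probability `p_support` an ALS backup
is requested when on-scene care starts; M — closest available BLS unless its
estimated travel time exceeds `tau_m_min` and a closer ALS is available.
Calls with no candidate queue in strict priority order (K > N > M, FIFO
within class) and the queue is re-examined at every release; an ambulance is
dispatchable when idle at base or returning.  The dual-dispatched ALS
completes its trip by default; a configurable cancel rule
(`cancel_support=True`) recalls it at the next node once the primary clears
the scene.

Service: on-scene time is lognormal with a (diagnosis, crew)-specific mean —
defaults 28 min BLS / 22 min ALS, cv 0.35, inside the 20–30 min band with
BLS above ALS; transport to hospital is Bernoulli (0.71 BLS / 0.53 ALS); the
destination is the nearest hospital admitting the patient's age class and
diagnosis (lowest id on ties); drop-off is Erlang per hospital with means in
the 14–38 min band (shape 3).  Response time is the interval from ambulance
assignment to the *first* scene arrival; thresholds (15 min overall, 8 min
for the First Hour Quintet) are inclusive.  Workload is busy time (from
assignment to base arrival, uninterrupted across re-dispatches) over the
horizon.  Crew shifts, technical breaks, and secondary inter-hospital
transfers are out of scope.

`p_support = 0.1` and `tau_m_min = 25` min are assumptions, not estimates:
no public figures exist for either, so they are configuration with
documented defaults.

Across replications, each indicator is reported as the mean with a
Student-t 95% CI (n−1 d.f.); deployments are compared by deltas with
disjoint-CI significance flags.  Calls still queued when the event list is
exhausted are censored: counted, logged, excluded from response-time
statistics.

## Synthetic country

The generator emulates the statistical structure of a mixed urban-rural
national EMS dataset: lognormal municipality populations (σ = 1.1) scaled to
a configured total; a connected road network from the Euclidean MST plus
2-nearest-neighbour shortcuts with a 1.25 winding factor; 250 m street grids
in the most populous towns (which are the urban stratum); one station per
~19k inhabitants with an ALS share of 0.3 (the national ratios);
hospitals in the largest towns; a bimodal hour-of-day arrival profile
(peaks 9–11 and 18–21, overnight trough) scaled to 0.13 calls per 1000
inhabitants per day; priority mix K 0.12 / N 0.55 / M 0.33 and a ten-entry
diagnosis distribution containing the First Hour Quintet — these mixes are
plausible synthetic defaults, not measured national truths.  Day-of-week and
month effects are flat by design.

The *current* deployment is apportioned to municipalities by population
multiplied by lognormal(0, 0.8) noise, emulating a historically grown
network that lags present demand — this is what gives the optimizer
something to improve, mirroring the premise of a redesign study.  Everything
is reproducible from one seed, and every artifact round-trips through the
package's CSV/YAML readers.

What passing tests on this world do *not* show: calibration to any real
country's geography, call volumes or speeds.  The synthetic network has no
one-way streets, turn restrictions or stochastic travel times, population is
static (no commuting), and the demand model has no seasonal or weekday
structure.  Results on synthetic worlds demonstrate correctness and
qualitative behaviour (monotone improvement with budget, urban/rural gap
narrowing), not quantitative forecasts.

## Problem sizes

Default desk-scale runs use the `tiny` preset (12 municipalities, 8
stations, one town grid), 30–60 days of synthetic history, and simulations
of 2–7 days × 2–3 replications; the full pipeline completes in seconds.  A
`slovakia-like` preset (320 municipalities, 274 stations / 86 ALS, 8 towns,
5.4 M inhabitants) reproduces the published scale ratios for generator
realism; its nationwide MIP is substantially heavier and is not part of the
default test runs.  The acceptance script verifies optimizer exactness on
200 random instances and budget monotonicity on 50, sizes at which
exhaustive enumeration remains a practical oracle.
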