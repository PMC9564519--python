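"""Performance indicators of an EMS deployment with replication CIs.

Response time is the interval from the dispatcher's ambulance assignment to
the first arrival at the scene.  Threshold coverages use inclusive
comparison (RT <= threshold).  Workload is the fraction of the horizon an
ambulance spends in non-idle states.  With multiple replications, each
indicator is the across-replication mean with a Student-t 95% confidence
interval (n-1 degrees of freedom).  Calls left unserved when the run ends
are excluded from response-time statistics but counted as censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .demand_model import FHQ_DIAGNOSES
from .simulator import ReplicationResult

RT_THRESHOLD_MIN = 15.0
FHQ_THRESHOLD_MIN = 8.0

INDICATOR_NAMES = (
    "mean_rt_K",
    "mean_rt_N",
    "mean_rt_M",
    "mean_rt_overall",
    "pct_within_15",
    "mean_rt_fhq",
    "pct_fhq_within_8",
    "workload_BLS_pct",
    "workload_ALS_pct",
    "total_mileage_km",
    "n_calls",
    "n_censored",
)


class IndicatorError(Exception):
    pass


@dataclass
class IndicatorReport:
    """Across-replication indicator means with 95% confidence intervals.

    ``values[name] = (mean, lo, hi)``; a stratum with no calls in any
    replication is absent from ``values`` rather than reported as zero.
    """

    n_replications: int
    values: dict[str, tuple[float, float, float]]
    strata: dict[str, dict[str, tuple[float, float, float]]] = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return self.values[name][0]

    def ci(self, name: str) -> tuple[float, float]:
        _, lo, hi = self.values[name]
        return lo, hi


def _response_times(log: ReplicationResult) -> list[tuple[str, str, float, object]]:
    """(priority, diagnosis, rt_min, zone_id) for every served call."""
    out = []
    for c in log.calls:
        rt = c.response_time_min
        if rt is None:
            continue
        if rt < 0:
            raise IndicatorError(f"negative response time for call {c.id}")
        out.append((c.priority, c.diagnosis, rt, c.zone_id))
    return out


def single_replication_indicators(
    log: ReplicationResult, grouping: Mapping | None = None
) -> dict[str, float | None]:
    """All indicators of one replication, recomputed from raw timestamps."""
    served = _response_times(log)
    vals: dict[str, float | None] = {}
    by_prio: dict[str, list[float]] = {"K": [], "N": [], "M": []}
    fhq: list[float] = []
    all_rt: list[float] = []
    for prio, diag, rt, _zone in served:
        by_prio[prio].append(rt)
        all_rt.append(rt)
        if diag in FHQ_DIAGNOSES:
            fhq.append(rt)
    for p in ("K", "N", "M"):
        vals[f"mean_rt_{p}"] = float(np.mean(by_prio[p])) if by_prio[p] else None
    vals["mean_rt_overall"] = float(np.mean(all_rt)) if all_rt else None
    vals["pct_within_15"] = (
        100.0 * float(np.mean([rt <= RT_THRESHOLD_MIN for rt in all_rt])) if all_rt else None
    )
    vals["mean_rt_fhq"] = float(np.mean(fhq)) if fhq else None
    vals["pct_fhq_within_8"] = (
        100.0 * float(np.mean([rt <= FHQ_THRESHOLD_MIN for rt in fhq])) if fhq else None
    )
    for kind in ("BLS", "ALS"):
        ambs = [a for a in log.ambulances if a.kind == kind]
        vals[f"workload_{kind}_pct"] = (
            100.0 * float(np.mean([a.busy_min / log.horizon_min for a in ambs]))
            if ambs
            else None
        )
    vals["total_mileage_km"] = log.total_mileage_km
    vals["n_calls"] = float(len(log.calls))
    vals["n_censored"] = float(log.n_censored)
    return vals


def _t_ci(samples: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    mean = float(np.mean(samples))
    n = len(samples)
    if n < 2 or np.allclose(samples, samples[0]):
        return mean, mean, mean
    half = stats.t.ppf(0.5 + level / 2, n - 1) * float(np.std(samples, ddof=1)) / np.sqrt(n)
    return mean, mean - half, mean + half


def compute_indicators(
    logs: ReplicationResult | Sequence[ReplicationResult],
    grouping: Mapping | None = None,
) -> IndicatorReport:
    """Indicator report over one or more replications.

    ``grouping`` optionally maps zone id -> stratum label (district or
    urban/rural); per-stratum mean response times are then reported under
    ``strata``.
    """
    if isinstance(logs, ReplicationResult):
        logs = [logs]
    per_rep = [single_replication_indicators(log) for log in logs]
    values: dict[str, tuple[float, float, float]] = {}
    for name in INDICATOR_NAMES:
        samples = [r[name] for r in per_rep if r[name] is not None]
        if not samples:
            continue
        values[name] = _t_ci(np.asarray(samples, dtype=float))
    strata: dict[str, dict] = {}
    if grouping is not None:
        per_rep_strata: dict[str, list[float]] = {}
        for log in logs:
            sums: dict[str, list[float]] = {}
            for _prio, _diag, rt, zone in _response_times(log):
                if zone not in grouping:
                    raise IndicatorError(f"call zone {zone!r} is unclassified")
                sums.setdefault(grouping[zone], []).append(rt)
            for label, rts in sums.items():
                per_rep_strata.setdefault(label, []).append(float(np.mean(rts)))
        for label, samples in sorted(per_rep_strata.items()):
            strata[label] = {"mean_rt": _t_ci(np.asarray(samples))}
    return IndicatorReport(n_replications=len(logs), values=values, strata=strata)


def compare_deployments(
    a: IndicatorReport, b: IndicatorReport
) -> dict[str, dict[str, float | bool]]:
    """Per-indicator deltas (B - A) with disjoint-95%-CI significance flags."""
    if a.n_replications != b.n_replications:
        raise IndicatorError("reports built from different replication counts")
    out: dict[str, dict[str, float | bool]] = {}
    for name in set(a.values) & set(b.values):
        ma, la, ha = a.values[name]
        mb, lb_, hb = b.values[name]
        out[name] = {
            "delta": mb - ma,
            "significant": bool(hb < la or ha < lb_),
        }
    return out


def urban_rural_report(
    logs: ReplicationResult | Sequence[ReplicationResult],
    classification: Mapping,
) -> dict[str, float]:
    """Mean response time per urban/rural class and their gap in seconds."""
    if isinstance(logs, ReplicationResult):
        logs = [logs]
    rts: dict[str, list[float]] = {}
    for log in logs:
        for _prio, _diag, rt, zone in _response_times(log):
            if zone not in classification:
                raise IndicatorError(f"call zone {zone!r} is unclassified")
            rts.setdefault(classification[zone], []).append(rt)
    out: dict[str, float] = {}
    for label, vals in rts.items():
        out[f"mean_rt_{label}_min"] = float(np.mean(vals))
    if "mean_rt_urban_min" in out and "mean_rt_rural_min" in out:
        out["gap_s"] = abs(out["mean_rt_urban_min"] - out["mean_rt_rural_min"]) * 60.0
    return out
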