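"""Independent brute-force oracles used to verify the optimizer and router.

These deliberately share no code with the package: placements are checked by
exhaustive subset enumeration and routes by simple-path enumeration.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np


def enumerate_lower_level(
    t: np.ndarray,
    b: np.ndarray,
    p: int,
    fixed_idx=(),
    current_idx=(),
    budget=None,
) -> float:
    """Optimal p-median cost by enumerating all candidate subsets."""
    n = t.shape[0]
    fixed = set(fixed_idx)
    current = set(current_idx)
    p_free = p - len(fixed)
    best = None
    for subset in combinations(range(n), p):
        s = set(subset)
        if not fixed <= s:
            continue
        if budget is not None and len(s & current) < p_free - budget:
            continue
        cost = float((t[sorted(s), :].min(axis=0) * b).sum())
        if best is None or cost < best:
            best = cost
    return best


def enumerate_upper_level(
    t: np.ndarray, b: np.ndarray, q: int, open_idx, fixed_als_idx=()
) -> float:
    """Optimal q-median cost over subsets of the open sites."""
    fixed = set(fixed_als_idx)
    best = None
    for subset in combinations(sorted(open_idx), q):
        if not fixed <= set(subset):
            continue
        cost = float((t[list(subset), :].min(axis=0) * b).sum())
        if best is None or cost < best:
            best = cost
    return best


def enumerate_route_time(network, speed_model, origin, dest, priority, depart_time):
    """Minimal travel time over all simple paths, evaluating edges at entry."""
    if origin == dest:
        return 0.0
    best = None
    for path in nx.all_simple_paths(network.graph, origin, dest):
        t = depart_time
        for a, bb in zip(path, path[1:]):
            d = network.graph[a][bb]
            s = speed_model.speed(
                d["category"], network.edge_built_up(a, bb), priority, time_min=t
            )
            t += d["length_km"] / s * 60.0
        total = t - depart_time
        if best is None or total < best:
            best = total
    return best
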