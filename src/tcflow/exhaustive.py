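"""Exhaustive integral-flow oracle for small instances.

Independent of the LP solver: enumerates all profitable S-to-T walks of a
flow problem (restricted to T2-crossing walks in strict mode), then
searches every integral assignment of flow units to those walks subject to
the arc capacities. Because every interaction cost is positive, an optimal
flow contains no circulation and uses only walks cheaper than the kappa1
reward, so the optimum over such assignments equals the optimum over all
integral feasible flows. Intended for instances of at most ~8 nodes with
small integral capacities, where the search is exact and fast; used to
cross-check the LP formulation.
"""

from __future__ import annotations

import itertools
import math
import random

from .errors import ConfigError
from .flow import SINK, SOURCE, Arc, FlowProblem

__all__ = ["exhaustive_optimum", "exhaustive_optima_count", "random_small_problem"]


def _candidate_walks(problem: FlowProblem) -> list[tuple[dict, float]]:
    """S-to-T walks with negative net objective, as arc-multiset footprints.

    A unit of flow may revisit a node (e.g. reach an intermediate regulator
    through a gene and come back through it afterwards), so enumeration is
    over walks, not simple paths; each arc is used at most its (integral)
    capacity times per walk. Because all interaction costs are positive and
    only walks whose total cost is below the kappa1 reward can improve the
    objective, the search is pruned once the accumulated cost reaches
    kappa1 — which also bounds the walk length. Walks with identical arc
    multisets are interchangeable and deduplicated.
    """
    out_arcs: dict[str, list[tuple[str, int]]] = {}
    for i, a in enumerate(problem.arcs):
        out_arcs.setdefault(a.u, []).append((a.v, i))
    arcs = problem.arcs
    need_transit = problem.mode == "temporal_strict"
    found: dict[frozenset, float] = {}

    def dfs(node: str, used: dict[int, int], cost: float, transited: bool) -> None:
        if node == SINK:
            if not need_transit or transited:
                key = frozenset(used.items())
                net = cost - problem.kappa1
                if key not in found or net < found[key]:
                    found[key] = net
            return
        for head, i in out_arcs.get(node, ()):
            cap = int(math.floor(arcs[i].capacity + 1e-9))
            if used.get(i, 0) >= cap:
                continue
            new_cost = cost + arcs[i].cost
            if new_cost >= problem.kappa1 - 1e-12:
                continue  # walk can no longer have negative net
            used[i] = used.get(i, 0) + 1
            dfs(head, used, new_cost, transited or head in problem.transits)
            used[i] -= 1
            if used[i] == 0:
                del used[i]

    dfs(SOURCE, {}, 0.0, False)
    return [(dict(key), net) for key, net in sorted(found.items(), key=repr)]


def _search(
    walks: list[tuple[dict, float]],
    caps: list[float],
    idx: int,
    acc: float,
    best: list[float],
    count_at: list[float] | None = None,
) -> None:
    if acc < best[0] - 1e-12:
        best[0] = acc
    if idx == len(walks):
        if count_at is not None and abs(acc - count_at[0]) <= 1e-9:
            count_at[1] += 1
        return
    footprint, net = walks[idx]
    max_units = min(
        int(math.floor(caps[i] / mult + 1e-9)) for i, mult in footprint.items()
    )
    # x = 0 branch first, then positive units
    _search(walks, caps, idx + 1, acc, best, count_at)
    for units in range(1, max_units + 1):
        for i, mult in footprint.items():
            caps[i] -= mult
        _search(walks, caps, idx + 1, acc + units * net, best, count_at)
    for i, mult in footprint.items():
        caps[i] += mult * max_units


def exhaustive_optimum(problem: FlowProblem) -> float:
    """Minimum objective over all integral feasible (transit-respecting) flows."""
    if problem.mode == "temporal_aggregate":
        raise ConfigError("exhaustive oracle supports strict and responsenet modes")
    walks = _candidate_walks(problem)
    caps = [a.capacity for a in problem.arcs]
    best = [0.0]
    _search(walks, caps, 0, 0.0, best)
    return best[0]


def exhaustive_optima_count(problem: FlowProblem) -> int:
    """Number of distinct integral path-assignments achieving the optimum.

    A count of 1 certifies a unique integral optimum (used to validate the
    stability analysis on instances known to be non-degenerate).
    """
    opt = exhaustive_optimum(problem)
    walks = _candidate_walks(problem)
    caps = [a.capacity for a in problem.arcs]
    counter = [opt, 0.0]
    best = [0.0]
    _search(walks, caps, 0, 0.0, best, count_at=counter)
    return int(counter[1])


def random_small_problem(
    rng: random.Random,
    mode: str = "temporal_strict",
    max_internal: int = 6,
) -> FlowProblem:
    """Random tiny flow instance with integral capacities <= 3.

    Internal nodes are randomly staged (at least one gene per stage); arc
    costs are drawn from the admissible cost range [0.2, 1]; direct
    T1-T3 arcs are never generated. kappa1 is drawn wide enough that both
    zero-flow and saturated optima occur across instances.
    """
    n = rng.randint(4, max_internal)
    names = [f"n{i}" for i in range(n)]
    t1 = {names[0]}
    t2 = {names[1]}
    t3 = {names[2]}
    for nm in names[3:]:
        r = rng.random()
        if r < 0.2:
            t1.add(nm)
        elif r < 0.4:
            t2.add(nm)
        elif r < 0.6:
            t3.add(nm)

    arcs: list[Arc] = []
    seen = set()
    for u, v in itertools.permutations(names, 2):
        if (u in t1 and v in t3) or (u in t3 and v in t1):
            continue
        if rng.random() < 0.45:
            cap = rng.randint(1, 3)
            cost = round(rng.uniform(0.2, 1.0), 2)
            arcs.append(Arc(u, v, capacity=float(cap), cost=cost, w=1.0 - cost))
            seen.add((u, v))
    for g in sorted(t1):
        arcs.append(Arc(SOURCE, g, capacity=float(rng.randint(1, 3)), cost=0.0))
    for g in sorted(t3):
        arcs.append(Arc(g, SINK, capacity=float(rng.randint(1, 3)), cost=0.0))
    kappa1 = round(rng.uniform(0.2, 3.0), 2)
    return FlowProblem(
        arcs=tuple(arcs),
        sources=frozenset(t1),
        transits=frozenset(t2),
        targets=frozenset(t3),
        kappa1=kappa1,
        mode=mode,
    )
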