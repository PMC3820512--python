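"""Minimum-cost flow formulation and solver for temporal sub-network inference.

The filtered, stage-labelled genes are wired into a single-commodity flow
problem over the scored interaction network: an auxiliary source S feeds the
initial-response genes (T1), the late effectors (T3) drain into an auxiliary
sink T, and every unit of flow is required to transit at least one
intermediate regulator (T2). Arc costs are inversely related to interaction
reliability (a = 1 - w'), arc capacities encode the relative fold change and
abundance of the adjacent staged gene, and the objective

    minimize  sum_ij a_ij f_ij  -  kappa1 * sum_{g in T1} f_{S,g}

rewards flow leaving the source, so the optimum balances path cost against
the kappa1 reward per unit. Three modes are provided:

* ``temporal_strict`` (default) — the transit requirement is enforced
  exactly by a two-layer graph transform: every non-T2 node is duplicated
  into a pre-transit and a post-transit copy, arcs stay within their layer,
  T2 nodes bridge the layers (entered from either layer, exited into the
  post layer), S attaches to the pre layer and T to the post layer. Every
  unit of S-to-T flow therefore crosses at least one T2 node. The two layer
  copies of an arc share the original capacity.
* ``temporal_aggregate`` — single layer plus the linear constraint
  sum(inflow(T2)) >= epsilon * outflow(S).
* ``responsenet`` — the non-temporal baseline: no transit requirement,
  interior capacities fixed at 1, the reward constant is gamma.

Solved as an LP with scipy's HiGHS backend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .errors import ConfigError, InfeasibleError, InternalError
from .expression import GeneStats, TimeGrouping
from .network import ScoredNetwork

__all__ = [
    "SOURCE",
    "SINK",
    "MODES",
    "Arc",
    "FlowProblem",
    "FlowSolution",
    "SweepResult",
    "default_capacity",
    "default_weight_adjust",
    "build_problem",
    "solve",
    "node_flows",
    "decompose_flow",
    "sweep_kappa",
    "responsenet_solve",
    "check_solution",
]

SOURCE = "__S__"
SINK = "__T__"
MODES = ("temporal_strict", "temporal_aggregate", "responsenet")

#: default capacity of arcs not incident to staged genes or terminals
OTHER_CAPACITY = 1.0


@dataclass(frozen=True)
class Arc:
    """A directed arc of the flow problem.

    ``w`` is the scaled interaction reliability (None on auxiliary S/T
    arcs); ``cost`` the per-unit flow cost; ``capacity`` the flow bound.
    """

    u: str
    v: str
    capacity: float
    cost: float
    w: float | None = None


@dataclass(frozen=True)
class FlowProblem:
    """An instantiated flow LP: arcs, stage sets and tuning constants.

    ``kappa1`` is the per-unit reward on S arcs (called gamma in
    responsenet mode); ``kappa2`` only matters at build time (it tunes
    T2-incident capacities) and is kept for provenance.
    """

    arcs: tuple[Arc, ...]
    sources: frozenset[str]
    transits: frozenset[str]
    targets: frozenset[str]
    kappa1: float
    kappa2: float = 0.0
    mode: str = "temporal_strict"
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.kappa1 < 0 or self.kappa2 < 0:
            raise ConfigError("kappa1 and kappa2 must be non-negative")
        stages = [self.sources, self.transits, self.targets]
        for a, b in ((0, 1), (0, 2), (1, 2)):
            if stages[a] & stages[b]:
                raise ConfigError("stage sets must be disjoint")
        for arc in self.arcs:
            if arc.capacity < 0:
                raise ConfigError(f"negative capacity on {arc.u} -> {arc.v}")
            if arc.u == SOURCE and arc.v not in self.sources:
                raise ConfigError(f"S arc to non-T1 node {arc.v!r}")
            if arc.v == SINK and arc.u not in self.targets:
                raise ConfigError(f"T arc from non-T3 node {arc.u!r}")
            if arc.v == SOURCE or arc.u == SINK:
                raise ConfigError("arcs may not enter S or leave T")
            if arc.u != SOURCE and arc.v != SINK and arc.cost <= 0:
                raise ConfigError(
                    f"network arc {arc.u} -> {arc.v} must have strictly positive cost"
                )
            if arc.u in self.sources and arc.v in self.targets:
                raise ConfigError(f"direct T1 -> T3 arc {arc.u} -> {arc.v} not allowed")
            if arc.u in self.targets and arc.v in self.sources:
                raise ConfigError(f"direct T3 -> T1 arc {arc.u} -> {arc.v} not allowed")


def default_capacity(F: float, e_bar: float, mean_F: float, mean_e: float) -> float:
    """Capacity of an arc parameterized by one staged gene.

    The first term is the gene's fold change relative to its stage-group
    mean (stronger induction, more capacity); the second its mean abundance
    relative to the group mean (better-supported transcripts, more
    capacity).
    """
    c = 0.0
    if mean_F > 0:
        c += F / mean_F
    if mean_e > 0:
        c += e_bar / mean_e
    return c


def default_weight_adjust(w: float, capacity: float, bonus_rate: float = 0.1) -> float:
    """Reliability bonus for arcs touching staged genes.

    The weight is raised in proportion to the arc's capacity and capped at
    0.8 so the derived cost 1 - w' never drops below 0.2.
    """
    return min(0.8, w * (1.0 + bonus_rate * capacity))


def _stats_map(stats) -> dict[str, GeneStats]:
    if isinstance(stats, Mapping):
        return dict(stats)
    return {s.gene_id: s for s in stats}


def build_problem(
    network: ScoredNetwork,
    grouping: TimeGrouping,
    stats,
    kappa1: float,
    kappa2: float = 0.0,
    mode: str = "temporal_strict",
    epsilon: float = 1.0,
    capacity_fn: Callable[[float, float, float, float], float] = default_capacity,
    weight_adjust_fn: Callable[[float, float], float] = default_weight_adjust,
    other_capacity: float = OTHER_CAPACITY,
    warn: bool = True,
) -> FlowProblem:
    """Wire a scored network and a stage grouping into a flow LP.

    Capacities: S->T1 and T3->T arcs are parameterized by the terminal
    gene's fold change and abundance (normalized by stage-group means);
    arcs incident to T2 genes by the T2 gene's statistics only — so path
    selection inside the network reflects the intermediate regulators —
    plus a ``kappa2 * w`` tuning term; all remaining arcs get a constant
    capacity (default 1). In responsenet mode every interior capacity is 1.

    Costs: a = 1 - w' with w' the reliability, boosted for arcs touching
    staged genes in proportion to their (temporal) capacity and capped at
    0.8. Costs are identical across modes. Direct arcs between T1 and T3
    genes are excluded; auxiliary S/T arcs carry zero cost.
    """
    if grouping.windows.names != ("T1", "T2", "T3") and len(grouping.windows.names) != 3:
        raise ConfigError("grouping must define exactly three stages")
    w1, w2, w3 = grouping.windows.names
    stat = _stats_map(stats)

    stage_sets: dict[str, list[str]] = {}
    for name in (w1, w2, w3):
        genes = [g for g in grouping.genes_in(name) if network.has_node(g)]
        missing = set(grouping.genes_in(name)) - set(genes)
        if missing and warn:
            warnings.warn(
                f"{len(missing)} {name} gene(s) absent from network: "
                f"{sorted(missing)[:5]}..."
            )
        if not genes:
            raise InfeasibleError(f"stage {name} has no genes present in the network")
        stage_sets[name] = genes

    t1, t2, t3 = (frozenset(stage_sets[n]) for n in (w1, w2, w3))
    staged = t1 | t2 | t3

    means: dict[str, tuple[float, float]] = {}
    for name in (w1, w2, w3):
        genes = [g for g in stage_sets[name] if g in stat]
        if genes:
            mF = float(np.mean([stat[g].F_i for g in genes]))
            me = float(np.mean([stat[g].e_bar_i for g in genes]))
        else:
            mF = me = 0.0
        means[name] = (mF, me)
    stage_of = {g: n for n in (w1, w2, w3) for g in stage_sets[n]}

    def gene_capacity(g: str) -> float:
        st = stat.get(g)
        if st is None:
            return other_capacity
        mF, me = means[stage_of[g]]
        return capacity_fn(st.F_i, st.e_bar_i, mF, me)

    arcs: list[Arc] = []
    for u, v, data in network.arcs():
        if u == v:
            continue
        if (u in t1 and v in t3) or (u in t3 and v in t1):
            continue  # direct initial-to-late arcs are excluded
        w = data["w"]
        # temporal capacity (also drives the cost adjustment in all modes)
        if v in t2:
            cap_t = gene_capacity(v) + kappa2 * w
        elif u in t2:
            cap_t = gene_capacity(u) + kappa2 * w
        else:
            cap_t = other_capacity
        if u in staged or v in staged:
            w_adj = weight_adjust_fn(w, cap_t)
        else:
            w_adj = w
        cost = 1.0 - w_adj
        cap = other_capacity if mode == "responsenet" else cap_t
        arcs.append(Arc(u, v, capacity=cap, cost=cost, w=w))

    for g in sorted(t1):
        arcs.append(Arc(SOURCE, g, capacity=gene_capacity(g), cost=0.0))
    for g in sorted(t3):
        arcs.append(Arc(g, SINK, capacity=gene_capacity(g), cost=0.0))

    return FlowProblem(
        arcs=tuple(arcs),
        sources=t1,
        transits=t2,
        targets=t3,
        kappa1=kappa1,
        kappa2=kappa2,
        mode=mode,
        epsilon=epsilon,
    )


# ---------------------------------------------------------------------------
# LP assembly and solving


@dataclass
class _LPData:
    """Assembled LP pieces, kept on the solution for stability re-solves."""

    var_arcs: list[tuple[object, object, int]]  # (tail, head, original arc index)
    c: np.ndarray
    A_eq: sparse.csr_matrix
    b_eq: np.ndarray
    A_ub: sparse.csr_matrix | None
    b_ub: np.ndarray | None
    bounds: list[tuple[float, float]]
    nodes: list


def _layer_arcs(problem: FlowProblem) -> list[tuple[object, object, int]]:
    """Variable arcs of the (possibly layered) LP graph.

    In strict mode each non-T2 node u becomes ("pre", u) and ("post", u);
    T2 nodes stay single. Arcs between non-T2 nodes exist in both layers
    (sharing the original capacity), arcs into a T2 node enter from either
    layer, and arcs leaving a T2 node enter the post layer, so the sink —
    attached to the post layer — is only reachable through a T2 node.
    """
    t2 = problem.transits
    out: list[tuple[object, object, int]] = []
    if problem.mode != "temporal_strict":
        for i, a in enumerate(problem.arcs):
            out.append((a.u, a.v, i))
        return out
    for i, a in enumerate(problem.arcs):
        u, v = a.u, a.v
        if u == SOURCE:
            out.append((SOURCE, ("pre", v), i))
        elif v == SINK:
            out.append((("post", u), SINK, i))
        elif u in t2 and v in t2:
            out.append((("mid", u), ("mid", v), i))
        elif v in t2:
            out.append((("pre", u), ("mid", v), i))
            out.append((("post", u), ("mid", v), i))
        elif u in t2:
            out.append((("mid", u), ("post", v), i))
        else:
            out.append((("pre", u), ("pre", v), i))
            out.append((("post", u), ("post", v), i))
    return out


def _assemble(problem: FlowProblem) -> _LPData:
    var_arcs = _layer_arcs(problem)
    n = len(var_arcs)
    arcs = problem.arcs

    c = np.zeros(n)
    for j, (tail, _head, i) in enumerate(var_arcs):
        c[j] = arcs[i].cost
        if tail == SOURCE:
            c[j] -= problem.kappa1

    all_endpoints = {t for t, _, _ in var_arcs} | {h for _, h, _ in var_arcs}
    nodes = sorted((nd for nd in all_endpoints if nd not in (SOURCE, SINK)), key=repr)
    nidx = {nd: k for k, nd in enumerate(nodes)}

    rows, cols, vals = [], [], []
    for j, (tail, head, _i) in enumerate(var_arcs):
        if tail in nidx:
            rows.append(nidx[tail])
            cols.append(j)
            vals.append(-1.0)
        if head in nidx:
            rows.append(nidx[head])
            cols.append(j)
            vals.append(1.0)
    A_eq = sparse.csr_matrix((vals, (rows, cols)), shape=(len(nodes), n))
    b_eq = np.zeros(len(nodes))

    # shared capacity across layer copies of the same original arc
    copies: dict[int, list[int]] = {}
    for j, (_t, _h, i) in enumerate(var_arcs):
        copies.setdefault(i, []).append(j)
    ub_rows, ub_cols, ub_vals, b_ub_list = [], [], [], []
    r = 0
    for i, js in copies.items():
        if len(js) > 1:
            for j in js:
                ub_rows.append(r)
                ub_cols.append(j)
                ub_vals.append(1.0)
            b_ub_list.append(arcs[i].capacity)
            r += 1

    if problem.mode == "temporal_aggregate":
        # epsilon * outflow(S) - inflow(T2) <= 0
        for j, (tail, head, _i) in enumerate(var_arcs):
            coeff = 0.0
            if tail == SOURCE:
                coeff += problem.epsilon
            if head in problem.transits:
                coeff -= 1.0
            if coeff != 0.0:
                ub_rows.append(r)
                ub_cols.append(j)
                ub_vals.append(coeff)
        b_ub_list.append(0.0)
        r += 1

    if b_ub_list:
        A_ub = sparse.csr_matrix((ub_vals, (ub_rows, ub_cols)), shape=(r, n))
        b_ub = np.array(b_ub_list)
    else:
        A_ub, b_ub = None, None

    bounds = [(0.0, arcs[i].capacity) for _t, _h, i in var_arcs]
    return _LPData(var_arcs, c, A_eq, b_eq, A_ub, b_ub, bounds, nodes)


@dataclass
class FlowSolution:
    """Solved flow problem with flows mapped back to the original arcs."""

    problem: FlowProblem
    arc_flows: dict[tuple[str, str], float]
    objective: float
    status: str
    active_tol: float = 1e-6
    _lp: _LPData | None = field(default=None, repr=False)
    _x: np.ndarray | None = field(default=None, repr=False)

    def node_flows(self) -> dict[str, float]:
        """Sum of incoming arc flows per gene (S and T excluded)."""
        nf: dict[str, float] = {}
        for (u, v), f in self.arc_flows.items():
            if u != SOURCE:
                nf.setdefault(u, 0.0)
            if v != SINK:
                nf[v] = nf.get(v, 0.0) + f
        return nf

    def active_arcs(self, include_terminal: bool = False) -> list[tuple[str, str]]:
        out = []
        for (u, v), f in sorted(self.arc_flows.items()):
            if f <= self.active_tol:
                continue
            if not include_terminal and (u == SOURCE or v == SINK):
                continue
            out.append((u, v))
        return out

    def high_confidence_genes(self, threshold: float = 1.0) -> set[str]:
        """Genes with node flow above the high-confidence threshold."""
        return {g for g, f in self.node_flows().items() if f > threshold}

    @property
    def outflow_source(self) -> float:
        return sum(f for (u, _v), f in self.arc_flows.items() if u == SOURCE)

    @property
    def inflow_sink(self) -> float:
        return sum(f for (_u, v), f in self.arc_flows.items() if v == SINK)


def solve(problem: FlowProblem, active_tol: float = 1e-6) -> FlowSolution:
    """Solve the flow LP with HiGHS and map layer flows back to arcs."""
    lp = _assemble(problem)
    res = linprog(
        lp.c,
        A_ub=lp.A_ub,
        b_ub=lp.b_ub,
        A_eq=lp.A_eq,
        b_eq=lp.b_eq,
        bounds=lp.bounds,
        method="highs",
    )
    if res.status != 0:
        raise InfeasibleError(
            f"LP solve failed (status {res.status}: {res.message}); "
            f"mode={problem.mode}, kappa1={problem.kappa1}, kappa2={problem.kappa2}, "
            f"|arcs|={len(problem.arcs)}"
        )
    x = np.maximum(res.x, 0.0)
    arc_flows: dict[tuple[str, str], float] = {(a.u, a.v): 0.0 for a in problem.arcs}
    for j, (_t, _h, i) in enumerate(lp.var_arcs):
        a = problem.arcs[i]
        arc_flows[(a.u, a.v)] += x[j]
    return FlowSolution(
        problem=problem,
        arc_flows=arc_flows,
        objective=float(res.fun),
        status="optimal",
        active_tol=active_tol,
        _lp=lp,
        _x=x,
    )


def node_flows(solution: FlowSolution) -> dict[str, float]:
    """Per-gene flow: the sum of all incoming arc flows (S excluded)."""
    return solution.node_flows()


def check_solution(solution: FlowSolution, rtol: float = 1e-9) -> None:
    """Verify conservation and capacity feasibility; raise InternalError."""
    lp = solution._lp
    x = solution._x
    if lp is None or x is None:
        raise InternalError("solution lacks LP internals")
    inflow = {nd: 0.0 for nd in lp.nodes}
    outflow = {nd: 0.0 for nd in lp.nodes}
    for j, (t, h, _i) in enumerate(lp.var_arcs):
        if t in inflow:
            outflow[t] += x[j]
        if h in inflow:
            inflow[h] += x[j]
    for nd in lp.nodes:
        if abs(inflow[nd] - outflow[nd]) > rtol * (1.0 + inflow[nd]):
            raise InternalError(f"conservation violated at node {nd!r}")
    caps = {(a.u, a.v): a.capacity for a in solution.problem.arcs}
    for key, f in solution.arc_flows.items():
        if f > caps[key] + rtol * (1.0 + caps[key]):
            raise InternalError(f"capacity violated on arc {key}")


def decompose_flow(
    solution: FlowSolution, tol: float = 1e-9
) -> list[tuple[tuple[str, ...], float]]:
    """Path decomposition of the solved flow.

    Operates on the internal (layered) graph — where every S-to-T path of a
    strict-mode solution provably crosses a T2 node — and maps node
    sequences back to gene identifiers. Returns (path, flow) pairs whose
    flows sum to the source outflow. Residual circulation (absent from
    minimum-cost optima, which contain no positive-cost cycles) is
    discarded after verification.
    """
    lp = solution._lp
    if lp is None:
        raise InternalError("solution lacks LP internals")
    resid: dict[tuple, float] = {}
    succ: dict[object, set] = {}
    for j, (t, h, _i) in enumerate(lp.var_arcs):
        f = float(solution._x[j])
        if f > tol:
            resid[(t, h)] = resid.get((t, h), 0.0) + f
            succ.setdefault(t, set()).add(h)

    def find_path() -> list | None:
        stack = [(SOURCE, [SOURCE])]
        seen = set()
        while stack:
            node, path = stack.pop()
            if node == SINK:
                return path
            if node in seen:
                continue
            seen.add(node)
            for nxt in sorted(succ.get(node, ()), key=repr):
                if resid.get((node, nxt), 0.0) > tol:
                    stack.append((nxt, path + [nxt]))
        return None

    paths: list[tuple[tuple[str, ...], float]] = []
    while True:
        p = find_path()
        if p is None:
            break
        f = min(resid[(a, b)] for a, b in zip(p, p[1:]))
        for a, b in zip(p, p[1:]):
            resid[(a, b)] -= f
        mapped = tuple(
            nd if isinstance(nd, str) else nd[1] for nd in p
        )
        paths.append((mapped, f))

    total = sum(f for _p, f in paths)
    if abs(total - solution.outflow_source) > 1e-6 * (1.0 + total):
        raise InternalError(
            "flow decomposition does not account for the source outflow "
            f"({total} vs {solution.outflow_source}); conservation violated?"
        )
    return paths


# ---------------------------------------------------------------------------
# kappa sweep


@dataclass
class SweepResult:
    """Outcome of the (kappa1, kappa2) grid sweep."""

    kappa1: float
    kappa2: float
    solution: FlowSolution
    table: list[dict]
    meets_cap: bool


def default_kappa_grid(stop: float = 5.0, step: float = 0.5) -> list[tuple[float, float]]:
    ks = [round(k * step, 10) for k in range(int(round(stop / step)) + 1)]
    return [(k1, k2) for k1 in ks for k2 in ks]


def sweep_kappa(
    network: ScoredNetwork,
    grouping: TimeGrouping,
    stats,
    grid: Iterable[tuple[float, float]] | None = None,
    mode: str = "temporal_strict",
    unreliable_weight: float = 0.5,
    max_unreliable_fraction: float = 0.01,
    **build_kwargs,
) -> SweepResult:
    """Grid search over (kappa1, kappa2), default 0..5 in steps of 0.5.

    Among solutions whose active sub-network has fewer than 1% unreliable
    arcs (reliability w < 0.5), the one activating the most T1 source genes
    wins; ties break toward smaller kappa1, then kappa2. If no grid point
    meets the cap, the minimal-violation solution is returned with a
    warning.
    """
    if grid is None:
        grid = default_kappa_grid()
    grid = sorted(set(grid))
    if not grid:
        raise ConfigError("kappa grid must be non-empty")

    w_of: dict[tuple[str, str], float | None] = {}
    table: list[dict] = []
    best = None  # (n_sources, k1, k2, solution, frac)
    fallback = None  # minimal violation
    for k1, k2 in grid:
        problem = build_problem(
            network, grouping, stats, kappa1=k1, kappa2=k2, mode=mode,
            warn=False, **build_kwargs,
        )
        if not w_of:
            w_of = {(a.u, a.v): a.w for a in problem.arcs}
        sol = solve(problem)
        active = sol.active_arcs(include_terminal=False)
        n_unrel = sum(1 for uv in active if (w_of.get(uv) or 0.0) < unreliable_weight)
        frac = n_unrel / len(active) if active else 0.0
        n_sources = sum(
            1
            for (u, v), f in sol.arc_flows.items()
            if u == SOURCE and f > sol.active_tol
        )
        table.append(
            {
                "kappa1": k1,
                "kappa2": k2,
                "n_sources": n_sources,
                "active_arcs": len(active),
                "unreliable_fraction": frac,
                "objective": sol.objective,
            }
        )
        if frac < max_unreliable_fraction:
            if best is None or n_sources > best[0]:
                best = (n_sources, k1, k2, sol, frac)
        if fallback is None or (frac, -n_sources) < (fallback[4], -fallback[0]):
            fallback = (n_sources, k1, k2, sol, frac)

    if best is None:
        warnings.warn(
            "no kappa combination meets the unreliable-edge cap; "
            "returning the minimal-violation solution"
        )
        n_sources, k1, k2, sol, _f = fallback
        return SweepResult(k1, k2, sol, table, meets_cap=False)
    n_sources, k1, k2, sol, _f = best
    return SweepResult(k1, k2, sol, table, meets_cap=True)


def responsenet_solve(
    network: ScoredNetwork,
    grouping: TimeGrouping,
    stats,
    gamma: float = 0.5,
    **build_kwargs,
) -> FlowSolution:
    """Non-temporal baseline: no transit requirement, interior capacities 1.

    Source and sink arc capacities keep their expression-derived values;
    costs are identical to the temporal modes; gamma plays kappa1's role.
    """
    problem = build_problem(
        network, grouping, stats, kappa1=gamma, kappa2=0.0,
        mode="responsenet", **build_kwargs,
    )
    return solve(problem)
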