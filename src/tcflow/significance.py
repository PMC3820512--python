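"""Statistical support for the optimal sub-network.

Two complementary analyses:

* randomization p-values — the flow problem is re-solved many times with
  stage sets drawn uniformly at random from the network's genes (same sizes
  as the real stages). A gene's p-value is the fraction of random runs in
  which it re-appears at least as strongly as in the real optimum (node
  flow no smaller, and all of its optimally active incident interactions
  active again). Low p means the gene's placement is driven by the real
  expression staging, not by network topology alone.
* alternate-optima stability — with the objective pinned at the optimal
  value, each active arc's flow is alternately maximized and minimized
  (the flux-variability scheme of constraint-based metabolic modelling),
  bounding how much the reported sub-network could differ among equally
  optimal solutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .errors import InfeasibleError, InternalError
from .expression import GeneStats, TimeGrouping
from .flow import SINK, SOURCE, FlowSolution, build_problem, solve
from .network import ScoredNetwork

__all__ = [
    "SignificanceTable",
    "StabilityReport",
    "randomization_pvalues",
    "stability_analysis",
]


@dataclass
class SignificanceTable:
    """Per-gene randomization p-values with run provenance."""

    entries: dict[str, dict]  # gene -> {flow, count, p}
    R: int
    seed: int
    n_failed_runs: int = 0

    def pvalue(self, gene: str) -> float:
        return self.entries[gene]["p"]

    def genes(self) -> list[str]:
        return sorted(self.entries)


def _group_medians(
    grouping: TimeGrouping, stat: dict[str, GeneStats]
) -> dict[str, tuple[float, float]]:
    meds = {}
    for name in grouping.windows.names:
        genes = [g for g in grouping.genes_in(name) if g in stat]
        if genes:
            meds[name] = (
                float(np.median([stat[g].F_i for g in genes])),
                float(np.median([stat[g].e_bar_i for g in genes])),
            )
        else:
            meds[name] = (1.0, 1.0)
    return meds


def randomization_pvalues(
    network: ScoredNetwork,
    grouping: TimeGrouping,
    stats,
    solution: FlowSolution,
    R: int = 5000,
    seed: int = 0,
    smoothing: bool = False,
) -> SignificanceTable:
    """Randomization test: re-solve with random stage sets of the real sizes.

    The sampling universe is every gene in the network (auxiliary terminals
    excluded); the three stage sets are drawn disjoint and uniformly
    without replacement. Sampled genes keep their real expression
    statistics when available; genes never profiled fall back to the
    group-median fold change and abundance so capacities stay well-defined.
    kappa values and mode are taken from the solved problem. A run counts
    toward gene g when g's node flow is at least its optimal flow and every
    interaction incident to g that is active in the optimum is active in
    the random run. p = count / R (optionally (count+1)/(R+1)).
    """
    if R < 1:
        raise InfeasibleError("R must be >= 1")
    stat = {s.gene_id: s for s in stats} if not isinstance(stats, dict) else dict(stats)
    problem = solution.problem
    rng = np.random.default_rng(seed)
    universe = np.array(network.nodes)
    sizes = [grouping.counts[n] for n in grouping.windows.names]
    if len(universe) < sum(sizes):
        raise InfeasibleError(
            f"network has {len(universe)} genes; cannot sample "
            f"{sum(sizes)} disjoint staged genes"
        )

    nf_opt = solution.node_flows()
    tol = solution.active_tol
    active = set(solution.active_arcs(include_terminal=False))
    sub_genes = sorted(g for g, f in nf_opt.items() if f > tol)
    incident = {
        g: [(u, v) for (u, v) in active if u == g or v == g] for g in sub_genes
    }
    medians = _group_medians(grouping, stat)

    counts = {g: 0 for g in sub_genes}
    n_failed = 0
    for _run in range(R):
        perm = rng.permutation(len(universe))
        pick = universe[perm]
        assignment: dict[str, str] = {}
        run_stats: dict[str, GeneStats] = {}
        off = 0
        for name, size in zip(grouping.windows.names, sizes):
            for g in map(str, pick[off : off + size]):
                assignment[g] = name
                if g in stat:
                    run_stats[g] = stat[g]
                else:
                    mF, me = medians[name]
                    run_stats[g] = GeneStats(g, mF, me, {})
            off += size
        run_grouping = TimeGrouping(windows=grouping.windows, assignment=assignment)
        try:
            run_problem = build_problem(
                network,
                run_grouping,
                run_stats,
                kappa1=problem.kappa1,
                kappa2=problem.kappa2,
                mode=problem.mode,
                epsilon=problem.epsilon,
                warn=False,
            )
            run_sol = solve(run_problem)
        except InfeasibleError:
            n_failed += 1
            continue
        run_nf = run_sol.node_flows()
        run_active = {
            uv for uv, f in run_sol.arc_flows.items() if f > tol
        }
        for g in sub_genes:
            if run_nf.get(g, 0.0) < nf_opt[g] - 1e-9:
                continue
            if all(uv in run_active for uv in incident[g]):
                counts[g] += 1

    entries = {}
    for g in sub_genes:
        c = counts[g]
        p = (c + 1) / (R + 1) if smoothing else c / R
        entries[g] = {"flow": nf_opt[g], "count": c, "p": p}
    return SignificanceTable(entries=entries, R=R, seed=seed, n_failed_runs=n_failed)


@dataclass
class StabilityReport:
    """Flow bounds of every active arc across alternate optimal solutions."""

    arc_bounds: dict[tuple[str, str], tuple[float, float, float]]  # f*, fmin, fmax
    node_bounds: dict[str, tuple[float, float, float]]
    unchanged_arc_fraction: float
    unchanged_node_fraction: float
    n_solves: int
    tolerance: float


def stability_analysis(
    solution: FlowSolution, tolerance: float = 1e-6
) -> StabilityReport:
    """Bound each active arc's flow over the alternate-optima face.

    The optimal objective is fixed (within a small numeric slack) as an
    extra constraint, then each active arc's flow is maximized and
    minimized — two LPs per arc. An arc is "unchanged" when its bounds
    differ by less than ``tolerance``; a node is unchanged when all its
    incident active arcs are.
    """
    lp = solution._lp
    if lp is None:
        raise InternalError("solution lacks LP internals; re-solve first")
    problem = solution.problem
    opt = solution.objective

    # objective pin: c.x <= opt + slack (c.x >= opt holds for any feasible x)
    def pinned(slack: float):
        pin = sparse.csr_matrix(lp.c.reshape(1, -1))
        if lp.A_ub is not None:
            A = sparse.vstack([lp.A_ub, pin], format="csr")
            b = np.concatenate([lp.b_ub, [opt + slack]])
        else:
            A, b = pin, np.array([opt + slack])
        return A, b

    copies: dict[int, list[int]] = {}
    for j, (_t, _h, i) in enumerate(lp.var_arcs):
        copies.setdefault(i, []).append(j)
    arc_index = {(a.u, a.v): i for i, a in enumerate(problem.arcs)}

    active = [
        uv for uv, f in sorted(solution.arc_flows.items()) if f > solution.active_tol
    ]
    slack = 1e-9 * (1.0 + abs(opt))
    A_ub, b_ub = pinned(slack)

    def bound(uv: tuple[str, str], sense: float) -> float:
        js = copies[arc_index[uv]]
        c = np.zeros(len(lp.c))
        c[js] = sense  # +1 minimizes, -1 maximizes
        res = linprog(
            c, A_ub=A_ub, b_ub=b_ub, A_eq=lp.A_eq, b_eq=lp.b_eq,
            bounds=lp.bounds, method="highs",
        )
        if res.status != 0:
            raise InfeasibleError(f"stability bound LP failed for arc {uv}")
        return float(sense * res.fun)

    arc_bounds = {}
    n_solves = 0
    for uv in active:
        try:
            fmin = bound(uv, 1.0)
            fmax = bound(uv, -1.0)
        except InfeasibleError:
            # widen the objective pin once, then give up
            warnings.warn("stability bound LP infeasible; widening tolerance once")
            A_ub, b_ub = pinned(slack * 1e3)
            fmin = bound(uv, 1.0)
            fmax = bound(uv, -1.0)
        n_solves += 2
        arc_bounds[uv] = (solution.arc_flows[uv], fmin, fmax)

    unchanged = {uv for uv, (_f, lo, hi) in arc_bounds.items() if hi - lo < tolerance}
    frac_arcs = len(unchanged) / len(active) if active else 1.0

    node_arcs: dict[str, list[tuple[str, str]]] = {}
    for u, v in active:
        if u != SOURCE:
            node_arcs.setdefault(u, []).append((u, v))
        if v != SINK:
            node_arcs.setdefault(v, []).append((u, v))
    node_bounds = {}
    n_unchanged_nodes = 0
    for g, arcs_g in sorted(node_arcs.items()):
        inc = [uv for uv in arcs_g if uv[1] == g]
        f_star = sum(arc_bounds[uv][0] for uv in inc)
        lo = sum(arc_bounds[uv][1] for uv in inc)
        hi = sum(arc_bounds[uv][2] for uv in inc)
        node_bounds[g] = (f_star, lo, hi)
        if all(uv in unchanged for uv in arcs_g):
            n_unchanged_nodes += 1
    frac_nodes = n_unchanged_nodes / len(node_arcs) if node_arcs else 1.0

    return StabilityReport(
        arc_bounds=arc_bounds,
        node_bounds=node_bounds,
        unchanged_arc_fraction=frac_arcs,
        unchanged_node_fraction=frac_nodes,
        n_solves=n_solves,
        tolerance=tolerance,
    )
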