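"""Path extraction from the optimal sub-network.

Arcs of the active sub-network are given Opsahl-style lengths, the mean
flow divided by the arc's flow, so heavily used interactions are short and
weighted shortest paths preferentially follow high-flow routes. Hop-capped
shortest paths are computed between stage groups (the cap — default 3
arcs — is a hard constraint, so a label-setting dynamic program over
(node, hops) states is used instead of plain Dijkstra). Predicted paths
can be compared against user-supplied reference pathways, either as
directed edge lists (longest directed path present in both) or as gene
sets (co-membership fractions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .flow import SINK, SOURCE, FlowSolution

__all__ = [
    "PathRecord",
    "PathSet",
    "opsahl_lengths",
    "shortest_paths_between_stages",
    "match_directed_paths",
    "pathway_overlap_fraction",
]


@dataclass(frozen=True)
class PathRecord:
    source: str
    target: str
    nodes: tuple[str, ...]
    length: float
    hops: int
    source_stage: str
    target_stage: str


@dataclass
class PathSet:
    paths: list[PathRecord]
    hop_cap: int

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self):
        return iter(self.paths)


def opsahl_lengths(
    solution: FlowSolution, tol: float | None = None
) -> dict[tuple[str, str], float]:
    """Arc lengths f_bar / f over the active sub-network.

    f_bar is the mean flow over active interaction arcs (auxiliary S/T arcs
    excluded); an arc carrying exactly the mean flow has length 1. Inactive
    arcs are omitted. Returns an empty mapping when nothing is active.
    """
    tol = solution.active_tol if tol is None else tol
    flows = {
        uv: f
        for uv, f in solution.arc_flows.items()
        if f > tol and uv[0] != SOURCE and uv[1] != SINK
    }
    if not flows:
        return {}
    f_bar = sum(flows.values()) / len(flows)
    return {uv: f_bar / f for uv, f in flows.items()}


def shortest_paths_between_stages(
    solution: FlowSolution,
    lengths: Mapping[tuple[str, str], float] | None = None,
    hop_cap: int = 3,
    stage_pairs: Iterable[tuple[str, str]] | None = None,
) -> PathSet:
    """Hop-capped weighted shortest paths between stage groups.

    For each ordered stage pair (default: the consecutive pairs T1->T2 and
    T2->T3) and each endpoint pair, the minimum-Opsahl-length path with at
    most ``hop_cap`` arcs is found by dynamic programming over (node, hops)
    states. Ties break toward the lexicographically smallest node sequence;
    unreachable endpoint pairs are omitted.
    """
    if hop_cap < 1:
        raise ValueError("hop_cap must be >= 1")
    if lengths is None:
        lengths = opsahl_lengths(solution)
    problem = solution.problem
    stage_of = {}
    for g in problem.sources:
        stage_of[g] = "T1"
    for g in problem.transits:
        stage_of[g] = "T2"
    for g in problem.targets:
        stage_of[g] = "T3"
    if stage_pairs is None:
        stage_pairs = [("T1", "T2"), ("T2", "T3")]
    stage_genes = {
        "T1": sorted(problem.sources),
        "T2": sorted(problem.transits),
        "T3": sorted(problem.targets),
    }

    succ: dict[str, list[str]] = {}
    for u, v in lengths:
        succ.setdefault(u, []).append(v)
    for u in succ:
        succ[u].sort()

    records: list[PathRecord] = []
    for a_stage, b_stage in stage_pairs:
        for src in stage_genes[a_stage]:
            if src not in succ:
                continue
            # best[(node, hops)] = (length, path tuple); expanded hop by hop
            best: dict[int, dict[str, tuple[float, tuple[str, ...]]]] = {
                0: {src: (0.0, (src,))}
            }
            overall: dict[str, tuple[float, tuple[str, ...]]] = {}
            for h in range(1, hop_cap + 1):
                layer: dict[str, tuple[float, tuple[str, ...]]] = {}
                for u, (dist, path) in best[h - 1].items():
                    for v in succ.get(u, ()):
                        if v in path:
                            continue  # simple paths only
                        cand = (dist + lengths[(u, v)], path + (v,))
                        if v not in layer or cand < layer[v]:
                            layer[v] = cand
                best[h] = layer
                for v, cand in layer.items():
                    if v not in overall or cand < overall[v]:
                        overall[v] = cand
            for tgt in stage_genes[b_stage]:
                if tgt == src or tgt not in overall:
                    continue
                dist, path = overall[tgt]
                records.append(
                    PathRecord(
                        source=src,
                        target=tgt,
                        nodes=path,
                        length=dist,
                        hops=len(path) - 1,
                        source_stage=a_stage,
                        target_stage=b_stage,
                    )
                )
    return PathSet(paths=records, hop_cap=hop_cap)


def _longest_path_from(
    node: str,
    succ: Mapping[str, set],
    visited: set,
    depth_cap: int,
) -> int:
    if depth_cap == 0:
        return 0
    best = 0
    for nxt in succ.get(node, ()):
        if nxt in visited:
            continue
        visited.add(nxt)
        cand = 1 + _longest_path_from(nxt, succ, visited, depth_cap - 1)
        visited.discard(nxt)
        best = max(best, cand)
    return best


def match_directed_paths(
    solution: FlowSolution,
    reference_pathways: Mapping[str, Iterable[tuple[str, str]]],
    depth_cap: int = 8,
) -> dict[str, int]:
    """Longest directed path shared by the active sub-network and each
    reference pathway.

    The arc sets are intersected (directed, exact node-identifier match)
    and the longest simple directed path of the intersection graph is found
    by depth-limited search. Returns edges-per-pathway; 0 when nothing is
    shared.
    """
    active = set(solution.active_arcs(include_terminal=False))
    out: dict[str, int] = {}
    for pid, edges in reference_pathways.items():
        common = sorted(set(map(tuple, edges)) & active)
        succ: dict[str, set] = {}
        for u, v in common:
            succ.setdefault(u, set()).add(v)
        best = 0
        for start in succ:
            best = max(best, _longest_path_from(start, succ, {start}, depth_cap))
        out[pid] = best
    return out


def pathway_overlap_fraction(
    path_set: PathSet,
    pathway_gene_sets: Mapping[str, Iterable[str]],
    k: int = 2,
) -> dict[str, float | None]:
    """Fraction of predicted paths co-occurring in a reference gene set.

    Reports the fraction of paths with at least ``k`` member genes inside a
    single reference set ('at_least_k') and the fraction with all their
    genes inside one set ('all_genes'). Undefined (None) for an empty path
    set.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(path_set) == 0:
        return {"at_least_k": None, "all_genes": None}
    sets = {pid: set(genes) for pid, genes in pathway_gene_sets.items()}
    n_k = 0
    n_all = 0
    for rec in path_set:
        genes = set(rec.nodes)
        if any(len(genes & s) >= k for s in sets.values()):
            n_k += 1
        if any(genes <= s for s in sets.values()):
            n_all += 1
    n = len(path_set)
    return {"at_least_k": n_k / n, "all_genes": n_all / n}
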