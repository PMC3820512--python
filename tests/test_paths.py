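"""Opsahl lengths, hop-capped shortest paths and reference-pathway matching."""

import itertools

import pytest

from tcflow.flow import SINK, SOURCE, Arc, FlowProblem, FlowSolution, solve
from tcflow.paths import (
    match_directed_paths,
    opsahl_lengths,
    pathway_overlap_fraction,
    shortest_paths_between_stages,
)


def solution_with_flows(arc_flows, sources=(), transits=(), targets=()):
    """Assemble a FlowSolution directly from an arc->flow mapping."""
    arcs = tuple(
        Arc(u, v, capacity=10.0, cost=0.2, w=0.8) for (u, v) in arc_flows
    )
    problem = FlowProblem(
        arcs=arcs,
        sources=frozenset(sources),
        transits=frozenset(transits),
        targets=frozenset(targets),
        kappa1=1.0,
    )
    return FlowSolution(
        problem=problem, arc_flows=dict(arc_flows), objective=0.0, status="optimal"
    )


class TestOpsahl:
    def test_ratio_form(self):
        sol = solution_with_flows(
            {("a", "b"): 4.0, ("b", "c"): 2.0, ("c", "d"): 0.0},
            sources=["a"], transits=["b"], targets=["d"],
        )
        lengths = opsahl_lengths(sol)
        f_bar = (4.0 + 2.0) / 2
        assert lengths[("a", "b")] == pytest.approx(f_bar / 4.0)  # 0.75
        assert lengths[("b", "c")] == pytest.approx(f_bar / 2.0)  # 1.5
        assert ("c", "d") not in lengths  # inactive arcs excluded

    def test_mean_flow_arc_has_length_one(self):
        sol = solution_with_flows(
            {("a", "b"): 2.0, ("b", "c"): 4.0},
            sources=["a"], transits=["b"], targets=["c"],
        )
        lengths = opsahl_lengths(sol)
        assert lengths[("a", "b")] * 2.0 == pytest.approx(lengths[("b", "c")] * 4.0)
        # all-equal flows reduce to the unweighted case: every length exactly 1
        sol2 = solution_with_flows(
            {("a", "b"): 5.0, ("b", "c"): 5.0},
            sources=["a"], transits=["b"], targets=["c"],
        )
        assert all(v == 1.0 for v in opsahl_lengths(sol2).values())

    def test_empty_when_nothing_active(self):
        sol = solution_with_flows(
            {("a", "b"): 0.0}, sources=["a"], transits=["b"], targets=["c"]
        )
        sol.problem  # construction sanity
        assert opsahl_lengths(sol) == {}


def enumerate_shortest(lengths, src, tgt, cap):
    """Brute-force minimum over all simple paths of at most ``cap`` arcs."""
    succ = {}
    for u, v in lengths:
        succ.setdefault(u, []).append(v)
    best = None
    stack = [(src, (src,), 0.0)]
    while stack:
        node, path, dist = stack.pop()
        if node == tgt and len(path) > 1:
            cand = (dist, path)
            if best is None or cand < best:
                best = cand
            continue
        if len(path) - 1 >= cap:
            continue
        for v in succ.get(node, []):
            if v not in path:
                stack.append((v, path + (v,), dist + lengths[(node, v)]))
    return best


class TestShortestPaths:
    def test_matches_exhaustive_enumeration(self, small_bundle):
        sol = small_bundle.solve()
        lengths = opsahl_lengths(sol)
        ps = shortest_paths_between_stages(sol, lengths, hop_cap=3)
        assert len(ps) > 0
        for rec in ps:
            best = enumerate_shortest(lengths, rec.source, rec.target, 3)
            assert best is not None
            assert rec.length == pytest.approx(best[0])
            assert rec.nodes == best[1]

    def test_hop_cap_omits_long_connections(self):
        flows = {
            ("a", "w1"): 1.0, ("w1", "w2"): 1.0, ("w2", "w3"): 1.0,
            ("w3", "z"): 1.0,
        }
        sol = solution_with_flows(
            flows, sources=["a"], transits=["w1"], targets=["z"]
        )
        lengths = opsahl_lengths(sol)
        ps = shortest_paths_between_stages(
            sol, lengths, hop_cap=3, stage_pairs=[("T1", "T3")]
        )
        assert len(ps) == 0  # only a 4-arc route exists
        ps4 = shortest_paths_between_stages(
            sol, lengths, hop_cap=4, stage_pairs=[("T1", "T3")]
        )
        assert [rec.hops for rec in ps4] == [4]

    def test_single_arc_connection(self):
        sol = solution_with_flows(
            {("a", "m"): 1.0, ("m", "z"): 1.0},
            sources=["a"], transits=["m"], targets=["z"],
        )
        ps = shortest_paths_between_stages(sol, hop_cap=3)
        by_pair = {(r.source, r.target): r for r in ps}
        assert by_pair[("a", "m")].nodes == ("a", "m")
        assert by_pair[("m", "z")].nodes == ("m", "z")


class TestReferenceMatching:
    def _cascade_solution(self, n=5):
        chain = [f"g{i}" for i in range(n + 1)]
        flows = {(u, v): 1.0 for u, v in zip(chain, chain[1:])}
        return (
            solution_with_flows(
                flows, sources=[chain[0]], transits=[chain[1]], targets=[chain[-1]]
            ),
            list(zip(chain, chain[1:])),
        )

    def test_self_reference_gives_longest_active_path(self):
        sol, edges = self._cascade_solution(5)
        assert match_directed_paths(sol, {"self": edges}) == {"self": 5}

    def test_disjoint_namespace_gives_zero(self):
        sol, _edges = self._cascade_solution(3)
        assert match_directed_paths(sol, {"other": [("q1", "q2")]}) == {"other": 0}

    def test_monotone_in_reference(self):
        sol, edges = self._cascade_solution(4)
        short = match_directed_paths(sol, {"p": edges[:2]})["p"]
        longer = match_directed_paths(sol, {"p": edges})["p"]
        assert short <= longer

    def test_overlap_fractions(self):
        sol = solution_with_flows(
            {("a", "m"): 1.0, ("m", "z"): 1.0},
            sources=["a"], transits=["m"], targets=["z"],
        )
        ps = shortest_paths_between_stages(sol, hop_cap=3)
        full = pathway_overlap_fraction(ps, {"p1": {"a", "m", "z"}}, k=2)
        assert full == {"at_least_k": 1.0, "all_genes": 1.0}
        singletons = pathway_overlap_fraction(ps, {"p1": {"a"}, "p2": {"m"}}, k=2)
        assert singletons["at_least_k"] == 0.0

    def test_empty_path_set_undefined(self):
        from tcflow.paths import PathSet

        out = pathway_overlap_fraction(PathSet([], 3), {"p": {"a"}}, k=2)
        assert out == {"at_least_k": None, "all_genes": None}
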