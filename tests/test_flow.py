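"""Flow LP construction, solving, decomposition and the kappa sweep."""

import random

import pytest

from tcflow.errors import ConfigError, InfeasibleError
from tcflow.exhaustive import exhaustive_optimum, random_small_problem
from tcflow.expression import DEFAULT_WINDOWS, GeneStats, TimeGrouping
from tcflow.flow import (
    SINK,
    SOURCE,
    Arc,
    FlowProblem,
    build_problem,
    check_solution,
    decompose_flow,
    default_kappa_grid,
    node_flows,
    responsenet_solve,
    solve,
    sweep_kappa,
)
from tests.conftest import make_diamond


class TestProblemValidation:
    def test_stage_wiring_rules(self):
        base = dict(
            sources=frozenset({"a"}), transits=frozenset({"m"}),
            targets=frozenset({"z"}), kappa1=1.0,
        )
        with pytest.raises(ConfigError):  # S arc to a non-source
            FlowProblem(arcs=(Arc(SOURCE, "m", 1, 0.0),), **base)
        with pytest.raises(ConfigError):  # T arc from a non-target
            FlowProblem(arcs=(Arc("m", SINK, 1, 0.0),), **base)
        with pytest.raises(ConfigError):  # direct T1 -> T3
            FlowProblem(arcs=(Arc("a", "z", 1, 0.5),), **base)
        with pytest.raises(ConfigError):  # zero-cost interior arc
            FlowProblem(arcs=(Arc("a", "m", 1, 0.0),), **base)

    def test_empty_stage_is_infeasible(self, small_bundle):
        grouping = TimeGrouping(
            windows=DEFAULT_WINDOWS,
            assignment={"C00_T1": "T1", "C00_T3": "T3"},  # no T2 gene
        )
        with pytest.raises(InfeasibleError):
            build_problem(
                small_bundle.network, grouping, small_bundle.stats,
                kappa1=0.5, warn=False,
            )


class TestBuildProblem:
    def test_direct_t1_t3_arcs_removed(self):
        from tcflow.network import InteractionRecord, build_network, scale_scores

        records = scale_scores(
            [
                InteractionRecord("a", "z", "tf_target", "db", 5.0),
                InteractionRecord("a", "m", "tf_target", "db", 5.0),
                InteractionRecord("m", "z", "tf_target", "db", 5.0),
            ]
        )
        net = build_network(records)
        grouping = TimeGrouping(
            windows=DEFAULT_WINDOWS,
            assignment={"a": "T1", "m": "T2", "z": "T3"},
        )
        stats = [GeneStats(g, 2.0, 50.0, {}) for g in "amz"]
        problem = build_problem(net, grouping, stats, kappa1=0.5, warn=False)
        pairs = {(a.u, a.v) for a in problem.arcs}
        assert ("a", "z") not in pairs
        assert ("a", "m") in pairs and ("m", "z") in pairs

    def test_unstaged_arc_cost_is_one_minus_w(self, study_bundle):
        problem = build_problem(
            study_bundle.network, study_bundle.grouping, study_bundle.stats,
            kappa1=0.5, warn=False,
        )
        staged = problem.sources | problem.transits | problem.targets
        checked = 0
        for a in problem.arcs:
            if a.u in (SOURCE,) or a.v in (SINK,):
                continue
            if a.u not in staged and a.v not in staged:
                assert a.cost == pytest.approx(1.0 - a.w)
                checked += 1
        assert checked > 0

    def test_kappa2_adds_reliability_term_to_t2_capacities(self, study_bundle):
        p0 = build_problem(
            study_bundle.network, study_bundle.grouping, study_bundle.stats,
            kappa1=0.5, kappa2=0.0, warn=False,
        )
        p5 = build_problem(
            study_bundle.network, study_bundle.grouping, study_bundle.stats,
            kappa1=0.5, kappa2=0.5, warn=False,
        )
        caps0 = {(a.u, a.v): a.capacity for a in p0.arcs}
        diffs = 0
        for a in p5.arcs:
            if a.u == SOURCE or a.v == SINK:
                continue
            if a.u in p5.transits or a.v in p5.transits:
                assert a.capacity == pytest.approx(caps0[(a.u, a.v)] + 0.5 * a.w)
                diffs += 1
            else:
                assert a.capacity == caps0[(a.u, a.v)]
        assert diffs > 0


class TestSolve:
    def test_zero_source_capacity_means_zero_flow(self):
        p = make_diamond("temporal_strict")
        arcs = tuple(
            Arc(a.u, a.v, 0.0 if a.u == SOURCE else a.capacity, a.cost, a.w)
            for a in p.arcs
        )
        sol = solve(FlowProblem(arcs, p.sources, p.transits, p.targets, p.kappa1))
        assert sol.objective == pytest.approx(0.0)
        assert all(f == pytest.approx(0.0) for f in sol.arc_flows.values())

    def test_diamond_routes_by_mode(self):
        strict = solve(make_diamond("temporal_strict"))
        assert strict.arc_flows[("A", "M")] == pytest.approx(1.0)
        assert strict.arc_flows[("A", "X")] == pytest.approx(0.0)
        baseline = solve(make_diamond("responsenet"))
        assert baseline.arc_flows[("A", "X")] == pytest.approx(1.0)
        assert baseline.arc_flows[("A", "M")] == pytest.approx(0.0)

    def test_node_flow_bookkeeping(self):
        arcs = (
            Arc(SOURCE, "a", 0.3, 0.0),
            Arc(SOURCE, "b", 0.7, 0.0),
            Arc("a", "m", 1.0, 0.2, 0.8),
            Arc("b", "m", 1.0, 0.2, 0.8),
            Arc("m", "z", 2.0, 0.2, 0.8),
            Arc("z", SINK, 2.0, 0.0),
        )
        p = FlowProblem(
            arcs, frozenset({"a", "b"}), frozenset({"m"}), frozenset({"z"}),
            kappa1=2.0,
        )
        sol = solve(p)
        nf = node_flows(sol)
        assert nf["m"] == pytest.approx(1.0)  # 0.3 + 0.7 merge at the T2 node
        assert nf["a"] == pytest.approx(0.3)  # the S arc counts as incoming
        assert SOURCE not in nf

    def test_conservation_and_capacity_on_study_fixture(self, study_bundle):
        for mode in ("temporal_strict", "temporal_aggregate", "responsenet"):
            sol = study_bundle.solve(mode=mode)
            check_solution(sol)

    def test_aggregate_mode_forces_t2_inflow(self):
        sol = solve(make_diamond("temporal_aggregate"))
        inflow_t2 = sol.arc_flows[("A", "M")]
        assert inflow_t2 >= sol.outflow_source - 1e-9
        assert sol.outflow_source == pytest.approx(1.0)


class TestDecomposition:
    def test_single_path(self):
        sol = solve(make_diamond("temporal_strict"))
        paths = decompose_flow(sol)
        assert paths == [((SOURCE, "A", "M", "D", SINK), pytest.approx(1.0))]

    def test_two_disjoint_paths(self):
        arcs = (
            Arc(SOURCE, "a", 1.0, 0.0),
            Arc(SOURCE, "b", 1.0, 0.0),
            Arc("a", "m1", 1.0, 0.2, 0.8),
            Arc("b", "m2", 1.0, 0.2, 0.8),
            Arc("m1", "z1", 1.0, 0.2, 0.8),
            Arc("m2", "z2", 1.0, 0.2, 0.8),
            Arc("z1", SINK, 1.0, 0.0),
            Arc("z2", SINK, 1.0, 0.0),
        )
        p = FlowProblem(
            arcs, frozenset({"a", "b"}), frozenset({"m1", "m2"}),
            frozenset({"z1", "z2"}), kappa1=2.0,
        )
        sol = solve(p)
        paths = decompose_flow(sol)
        assert len(paths) == 2
        assert sum(f for _n, f in paths) == pytest.approx(sol.outflow_source) == 2.0

    def test_strict_paths_always_transit(self, study_bundle):
        sol = study_bundle.solve()
        for path, _f in decompose_flow(sol):
            assert any(n in sol.problem.transits for n in path)


class TestOracle:
    @pytest.mark.parametrize("mode", ["temporal_strict", "responsenet"])
    def test_lp_equals_integral_optimum(self, mode):
        rng = random.Random(42)
        for _ in range(60):
            p = random_small_problem(rng, mode=mode)
            sol = solve(p)
            check_solution(sol)
            opt = exhaustive_optimum(p)
            assert sol.objective == pytest.approx(opt, abs=1e-7)

    def test_kappa1_monotone_in_source_outflow(self):
        rng = random.Random(7)
        for _ in range(20):
            p = random_small_problem(rng)
            flows = []
            for k1 in (0.5, 1.0, 2.0, 4.0):
                q = FlowProblem(
                    p.arcs, p.sources, p.transits, p.targets,
                    kappa1=k1, mode=p.mode,
                )
                flows.append(solve(q).outflow_source)
            assert all(a <= b + 1e-9 for a, b in zip(flows, flows[1:]))

    def test_mode_nesting(self):
        rng = random.Random(9)
        for _ in range(20):
            p = random_small_problem(rng, mode="temporal_strict")
            relaxed = FlowProblem(
                p.arcs, p.sources, p.transits, p.targets,
                kappa1=p.kappa1, mode="responsenet",
            )
            assert solve(relaxed).objective <= solve(p).objective + 1e-9


class TestSweep:
    def test_default_grid_size(self):
        grid = default_kappa_grid()
        assert len(grid) == 121
        assert (0.5, 0.0) in grid  # the published operating point

    def test_single_point_grid(self, small_bundle):
        result = sweep_kappa(
            small_bundle.network, small_bundle.grouping, small_bundle.stats,
            grid=[(0.5, 0.0)],
        )
        assert (result.kappa1, result.kappa2) == (0.5, 0.0)
        assert result.meets_cap

    def test_selects_most_sources_then_smallest_kappas(self, small_bundle):
        result = sweep_kappa(
            small_bundle.network, small_bundle.grouping, small_bundle.stats,
            grid=[(0.0, 0.0), (0.5, 0.0), (0.5, 0.5), (1.0, 0.0)],
        )
        table = {(r["kappa1"], r["kappa2"]): r for r in result.table}
        best_n = max(
            r["n_sources"] for r in result.table if r["unreliable_fraction"] < 0.01
        )
        assert table[(result.kappa1, result.kappa2)]["n_sources"] == best_n
        ties = sorted(
            (k1, k2)
            for (k1, k2), r in table.items()
            if r["n_sources"] == best_n and r["unreliable_fraction"] < 0.01
        )
        assert (result.kappa1, result.kappa2) == ties[0]


class TestResponseNet:
    def test_interior_capacities_are_one(self, small_bundle):
        sol = responsenet_solve(
            small_bundle.network, small_bundle.grouping, small_bundle.stats,
            gamma=0.5, warn=False,
        )
        for a in sol.problem.arcs:
            if a.u != SOURCE and a.v != SINK:
                assert a.capacity == 1.0

    def test_zero_gamma_means_zero_flow(self, small_bundle):
        sol = responsenet_solve(
            small_bundle.network, small_bundle.grouping, small_bundle.stats,
            gamma=0.0, warn=False,
        )
        assert sol.outflow_source == pytest.approx(0.0)
        assert sol.objective == pytest.approx(0.0)
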