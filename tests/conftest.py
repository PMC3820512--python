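"""Shared fixtures: small constructed flow problems and a planted-cascade
synthetic bundle, generated once per session."""

from __future__ import annotations

import pytest

from tcflow.expression import assign_time_groups, compute_gene_stats, filter_genes
from tcflow.flow import SINK, SOURCE, Arc, FlowProblem, build_problem, solve
from tcflow.network import build_network, scale_scores
from tcflow.simulate import FixtureSpec, generate


def make_diamond(mode: str) -> FlowProblem:
    """Diamond instance where the cheap route bypasses the T2 gene.

    S -> A -> X -> D -> T costs 0.6 per interior arc; the alternative via
    the intermediate regulator M costs 0.9 per interior arc. The source arc
    capacity of 1 forces a single unit, so the mode decides the route.
    """
    arcs = (
        Arc(SOURCE, "A", capacity=1.0, cost=0.0),
        Arc("A", "X", capacity=1.0, cost=0.6, w=0.4),
        Arc("X", "D", capacity=1.0, cost=0.6, w=0.4),
        Arc("A", "M", capacity=1.0, cost=0.9, w=0.1),
        Arc("M", "D", capacity=1.0, cost=0.9, w=0.1),
        Arc("D", SINK, capacity=2.0, cost=0.0),
    )
    return FlowProblem(
        arcs=arcs,
        sources=frozenset({"A"}),
        transits=frozenset({"M"}),
        targets=frozenset({"D"}),
        kappa1=2.0,
        mode=mode,
    )


def make_two_parallel_paths() -> FlowProblem:
    """Two identical-cost parallel routes sharing one unit of flow.

    The flow may split arbitrarily between B1 and B2 at the same objective,
    the canonical degenerate instance for alternate-optima analysis.
    """
    arcs = (
        Arc(SOURCE, "A", capacity=1.0, cost=0.0),
        Arc("A", "B1", capacity=1.0, cost=0.3, w=0.7),
        Arc("A", "B2", capacity=1.0, cost=0.3, w=0.7),
        Arc("B1", "C", capacity=1.0, cost=0.3, w=0.7),
        Arc("B2", "C", capacity=1.0, cost=0.3, w=0.7),
        Arc("C", SINK, capacity=1.0, cost=0.0),
    )
    return FlowProblem(
        arcs=arcs,
        sources=frozenset({"A"}),
        transits=frozenset({"B1", "B2"}),
        targets=frozenset({"C"}),
        kappa1=2.0,
        mode="temporal_strict",
    )


class Bundle:
    """Planted-cascade fixture prepared end to end."""

    def __init__(self, spec: FixtureSpec):
        self.spec = spec
        self.records, self.matrix, self.manifest = generate(spec)
        self.stats = compute_gene_stats(self.matrix)
        self.filtered = filter_genes(self.stats, self.matrix)
        self.grouping = assign_time_groups(self.stats)
        self.network = build_network(scale_scores(self.records))

    def solve(self, mode: str = "temporal_strict", kappa1: float = 0.5,
              kappa2: float = 0.0):
        problem = build_problem(
            self.network, self.grouping, self.stats,
            kappa1=kappa1, kappa2=kappa2, mode=mode, warn=False,
        )
        return solve(problem)


@pytest.fixture(scope="session")
def small_bundle() -> Bundle:
    """30 nodes, 3 cascades: quick solves for unit-level checks."""
    return Bundle(FixtureSpec(n_nodes=30, n_cascades=3, arc_density=3.0, seed=5))


@pytest.fixture(scope="session")
def study_bundle() -> Bundle:
    """The study-scale fixture: 300 nodes, 10 planted cascades."""
    return Bundle(FixtureSpec(seed=1))
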