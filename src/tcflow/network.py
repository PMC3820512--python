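"""Assembly of the reliability-weighted molecular interaction network.

Heterogeneous interaction records (protein-protein, TF-target,
post-translational modification, functional association, inhibition) from
multiple source databases are merged into one directed graph. Raw
reliability scores are scaled per source onto [0, 0.8] — curated sources
carry the sentinel score 999 and map uniformly to 0.8 — so that reliability
is comparable across sources and the derived arc cost 1 - w stays strictly
positive. Protein-protein interactions become arc pairs in both directions;
all other interaction types are uni-directional. Genes and their protein
products share a single node.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import networkx as nx

from .errors import InputError

__all__ = [
    "INTERACTION_TYPES",
    "CURATED_SENTINEL",
    "InteractionRecord",
    "ScoredNetwork",
    "scale_scores",
    "build_network",
    "apply_knockout",
]

INTERACTION_TYPES = frozenset({"ppi", "tf_target", "ptm", "functional", "inhibition"})

#: raw score assigned uniformly to manually curated interactions
CURATED_SENTINEL = 999.0


@dataclass(frozen=True)
class InteractionRecord:
    """One interaction as read from an interaction table.

    ``raw_score`` is the source database's own reliability value (arbitrary
    per-source scale, non-negative); ``w`` is filled in by
    :func:`scale_scores`.
    """

    source_node: str
    target_node: str
    interaction_type: str
    source_db: str
    raw_score: float
    w: float | None = None

    def __post_init__(self) -> None:
        if not self.source_node or not self.target_node:
            raise InputError("interaction nodes must be non-empty strings")
        if self.raw_score < 0:
            raise InputError(
                f"negative raw score {self.raw_score} for "
                f"{self.source_node} -> {self.target_node}"
            )


class ScoredNetwork:
    """Directed network with scaled reliability weights on every arc.

    Thin wrapper around a :class:`networkx.DiGraph` whose edges carry
    ``w`` (scaled reliability in [0, 0.8]), ``interaction_type`` and
    ``source_db`` attributes.
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def arcs(self) -> list[tuple[str, str, dict]]:
        return sorted(self.graph.edges(data=True), key=lambda e: (e[0], e[1]))

    @property
    def n_arcs(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["w"]

    def has_node(self, n: str) -> bool:
        return self.graph.has_node(n)

    def copy(self) -> "ScoredNetwork":
        return ScoredNetwork(self.graph.copy())


def scale_scores(
    records: Iterable[InteractionRecord], target_max: float = 0.8
) -> list[InteractionRecord]:
    """Min-max scale raw scores onto [0, target_max] within each source db.

    Each source database is scaled independently because raw scales are
    incomparable across sources: ``w = target_max * (r - r_min) / (r_max -
    r_min)``. A source with constant scores (including all-curated-999
    sources) maps uniformly to ``target_max``.
    """
    records = list(records)
    by_db: dict[str, list[float]] = {}
    for rec in records:
        by_db.setdefault(rec.source_db, []).append(rec.raw_score)
    bounds = {db: (min(v), max(v)) for db, v in by_db.items()}
    out = []
    for rec in records:
        lo, hi = bounds[rec.source_db]
        if hi == lo:
            w = target_max
        else:
            w = target_max * (rec.raw_score - lo) / (hi - lo)
        out.append(replace(rec, w=w))
    return out


def build_network(
    records: Iterable[InteractionRecord],
    node_rename: Mapping[str, str] | None = None,
) -> ScoredNetwork:
    """Build the directed scored network from scaled interaction records.

    ppi records contribute arcs in both directions with equal weight; all
    other types contribute a single arc. Duplicate arcs (same ordered node
    pair from any source) collapse to the maximum scaled weight. An optional
    ``node_rename`` mapping merges identifier namespaces (e.g. an ortholog
    or gene/protein symbol map); identity by default.
    """
    g = nx.DiGraph()
    rename = node_rename or {}
    for rec in records:
        if rec.interaction_type not in INTERACTION_TYPES:
            raise InputError(
                f"unknown interaction type {rec.interaction_type!r} for "
                f"{rec.source_node} -> {rec.target_node}"
            )
        if rec.w is None:
            raise InputError(
                "records must be scaled (w set) before building the network; "
                "call scale_scores first"
            )
        u = rename.get(rec.source_node, rec.source_node)
        v = rename.get(rec.target_node, rec.target_node)
        pairs = [(u, v), (v, u)] if rec.interaction_type == "ppi" else [(u, v)]
        for a, b in pairs:
            if g.has_edge(a, b) and g.edges[a, b]["w"] >= rec.w:
                continue
            g.add_edge(
                a,
                b,
                w=rec.w,
                interaction_type=rec.interaction_type,
                source_db=rec.source_db,
            )
    return ScoredNetwork(g)


def apply_knockout(
    network: ScoredNetwork,
    genes: Iterable[str],
    strict: bool = False,
    warn: bool = True,
) -> ScoredNetwork:
    """Remove knocked-out genes and all their incident arcs.

    Emulates knockout-cell analyses (e.g. MyD88- or Ticam1/TRIF-deficient
    cells): the node is deleted from the network before solving. Returns a
    new network; the original is untouched. Genes absent from the network
    are a warning and no-op by default, an error in strict mode.
    """
    import warnings

    out = network.copy()
    for gene in genes:
        if not out.graph.has_node(gene):
            if strict:
                raise InputError(f"knockout gene {gene!r} not in network")
            if warn:
                warnings.warn(f"knockout gene {gene!r} not in network; skipping")
            continue
        out.graph.remove_node(gene)
    return out
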