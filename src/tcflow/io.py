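"""Readers and writers for the package's tab-delimited table dialects.

All artifacts are plain TSV (UTF-8; gene identifiers are opaque
case-sensitive strings, unicode symbols preserved) plus JSON manifests.
Schema violations are reported with the file and 1-based line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import InputError
from .expression import ExpressionMatrix, GeneStats, TimeGrouping
from .flow import FlowSolution
from .network import InteractionRecord, ScoredNetwork
from .paths import PathSet
from .significance import SignificanceTable, StabilityReport

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_interactions_tsv",
    "write_interactions_tsv",
    "read_network_tsv",
    "write_network_tsv",
    "read_node_rename_tsv",
    "write_stats_tsv",
    "write_arc_table",
    "write_node_table",
    "write_significance_tsv",
    "write_stability_tsv",
    "write_paths_tsv",
    "write_pathway_match_tsv",
    "read_pathway_edges_tsv",
    "read_gene_sets_tsv",
    "write_manifest",
    "read_manifest",
]


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a gene x time matrix: header ``gene\\t<t0>\\t<t1>...`` in hours."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise InputError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise InputError(f"{path}:1: header must be 'gene\\t<time>...' columns")
    try:
        times = tuple(float(t) for t in header[1:])
    except ValueError as exc:
        raise InputError(f"{path}:1: time columns must parse as hours: {exc}") from None
    genes: list[str] = []
    rows: list[list[float]] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise InputError(
                f"{path}:{ln}: expected {len(header)} columns, got {len(parts)}"
            )
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise InputError(f"{path}:{ln}: non-numeric abundance: {exc}") from None
        genes.append(parts[0])
    return ExpressionMatrix(
        gene_ids=tuple(genes), times=times, values=np.array(rows, dtype=float)
    )


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(_fmt(t) for t in matrix.times) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gene + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_interactions_tsv(path: str | Path) -> list[InteractionRecord]:
    """Read an interaction table: source, target, type, source_db, score."""
    path = Path(path)
    out: list[InteractionRecord] = []
    with path.open(encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if ln == 1 and line.startswith("source\ttarget\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise InputError(f"{path}:{ln}: expected 5 columns, got {len(parts)}")
            u, v, itype, db, score = parts
            try:
                raw = float(score)
            except ValueError:
                raise InputError(f"{path}:{ln}: score column must be numeric") from None
            try:
                out.append(InteractionRecord(u, v, itype, db, raw))
            except InputError as exc:
                raise InputError(f"{path}:{ln}: {exc}") from None
    return out


def write_interactions_tsv(
    records: Iterable[InteractionRecord], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tinteraction_type\tsource_db\traw_score\n")
        for r in records:
            fh.write(
                f"{r.source_node}\t{r.target_node}\t{r.interaction_type}\t"
                f"{r.source_db}\t{_fmt(r.raw_score)}\n"
            )


def write_network_tsv(network: ScoredNetwork, path: str | Path) -> None:
    """Canonical scored-network table: u, v, type, db, scaled weight."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("u\tv\tinteraction_type\tsource_db\tw\n")
        for u, v, data in network.arcs():
            fh.write(
                f"{u}\t{v}\t{data['interaction_type']}\t{data['source_db']}\t"
                f"{_fmt(data['w'])}\n"
            )


def read_network_tsv(path: str | Path) -> ScoredNetwork:
    import networkx as nx

    path = Path(path)
    g = nx.DiGraph()
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("u\tv\t"):
            raise InputError(f"{path}:1: not a scored-network table")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise InputError(f"{path}:{ln}: expected 5 columns")
            u, v, itype, db, w = parts
            g.add_edge(u, v, w=float(w), interaction_type=itype, source_db=db)
    return ScoredNetwork(g)


def read_node_rename_tsv(path: str | Path) -> dict[str, str]:
    """Two-column node rename map (e.g. an externally produced ortholog map)."""
    path = Path(path)
    out: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{ln}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def write_stats_tsv(
    stats: Iterable[GeneStats],
    grouping: TimeGrouping | None,
    path: str | Path,
) -> None:
    """Gene statistics table: gene, F_i, e_bar_i, group, passes_filters."""
    path = Path(path)
    assign = grouping.assignment if grouping else {}
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\tF_i\te_bar_i\tgroup\tpasses_filters\n")
        for st in stats:
            fh.write(
                f"{st.gene_id}\t{_fmt(st.F_i)}\t{_fmt(st.e_bar_i)}\t"
                f"{assign.get(st.gene_id, '-')}\t{int(st.passes_filters)}\n"
            )


def write_arc_table(solution: FlowSolution, path: str | Path) -> None:
    """Arc table of a solved problem: u, v, w, capacity, cost, flow."""
    path = Path(path)
    arcs = {(a.u, a.v): a for a in solution.problem.arcs}
    with path.open("w", encoding="utf-8") as fh:
        fh.write("u\tv\tw\tcapacity\tcost\tflow\n")
        for (u, v), f in sorted(solution.arc_flows.items()):
            a = arcs[(u, v)]
            w = "-" if a.w is None else _fmt(a.w)
            fh.write(f"{u}\t{v}\t{w}\t{_fmt(a.capacity)}\t{_fmt(a.cost)}\t{_fmt(f)}\n")


def write_node_table(
    solution: FlowSolution,
    path: str | Path,
    significance: SignificanceTable | None = None,
) -> None:
    """Node table: gene, stage, flow, p-value (or '-' when not computed)."""
    path = Path(path)
    problem = solution.problem
    stage_of: dict[str, str] = {}
    for g in problem.sources:
        stage_of[g] = "T1"
    for g in problem.transits:
        stage_of[g] = "T2"
    for g in problem.targets:
        stage_of[g] = "T3"
    pv = significance.entries if significance else {}
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\tstage\tflow\tp_value\n")
        for g, f in sorted(solution.node_flows().items()):
            p = _fmt(pv[g]["p"]) if g in pv else "-"
            fh.write(f"{g}\t{stage_of.get(g, '-')}\t{_fmt(f)}\t{p}\n")


def write_significance_tsv(table: SignificanceTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\tflow\tqualifying_runs\tp_value\n")
        for g in table.genes():
            e = table.entries[g]
            fh.write(f"{g}\t{_fmt(e['flow'])}\t{e['count']}\t{_fmt(e['p'])}\n")


def write_stability_tsv(report: StabilityReport, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("u\tv\tflow\tf_min\tf_max\tunchanged\n")
        for (u, v), (f, lo, hi) in sorted(report.arc_bounds.items()):
            unchanged = int(hi - lo < report.tolerance)
            fh.write(f"{u}\t{v}\t{_fmt(f)}\t{_fmt(lo)}\t{_fmt(hi)}\t{unchanged}\n")


def write_paths_tsv(path_set: PathSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tstages\tnodes\tlength\thops\n")
        for rec in path_set:
            fh.write(
                f"{rec.source}\t{rec.target}\t{rec.source_stage}->{rec.target_stage}\t"
                f"{'|'.join(rec.nodes)}\t{_fmt(rec.length)}\t{rec.hops}\n"
            )


def write_pathway_match_tsv(matches: Mapping[str, int], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("pathway_id\tlongest_matched_path_edges\n")
        for pid in sorted(matches):
            fh.write(f"{pid}\t{matches[pid]}\n")


def read_pathway_edges_tsv(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Reference pathway edge lists: pathway_id, u, v."""
    path = Path(path)
    out: dict[str, list[tuple[str, str]]] = {}
    with path.open(encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#") or line.startswith("pathway_id\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise InputError(f"{path}:{ln}: expected 3 columns")
            out.setdefault(parts[0], []).append((parts[1], parts[2]))
    return out


def read_gene_sets_tsv(path: str | Path) -> dict[str, set[str]]:
    """Reference pathway gene sets: pathway_id, gene."""
    path = Path(path)
    out: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#") or line.startswith("pathway_id\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{ln}: expected 2 columns")
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(manifest, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
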