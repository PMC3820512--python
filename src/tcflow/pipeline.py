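"""End-to-end orchestration: configuration, run manifest and output tables.

``run_pipeline`` chains expression preparation, network assembly, optional
knockout deletion, the flow solve (fixed kappas or a grid sweep),
randomization significance, stability analysis and path extraction, and
writes every table plus a JSON manifest stamped with a hash of the
configuration and the seed. Re-running an identical configuration
reproduces identical tables (the solver and arc ordering are
deterministic).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import io as tio
from .errors import ConfigError
from .expression import (
    DEFAULT_WINDOWS,
    TimeWindows,
    assign_time_groups,
    compute_gene_stats,
    filter_genes,
)
from .flow import build_problem, solve, sweep_kappa
from .network import apply_knockout, build_network, scale_scores
from .paths import opsahl_lengths, shortest_paths_between_stages
from .significance import randomization_pvalues, stability_analysis

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    expression: str
    interactions: str
    out_dir: str
    node_rename: str | None = None
    used_times: list[float] | None = None
    windows: dict[str, list[float]] | None = None
    pseudocount: float = 1.0
    kappa1: float = 0.5
    kappa2: float = 0.0
    sweep: bool = False
    mode: str = "temporal_strict"
    epsilon: float = 1.0
    knockout: list[str] = field(default_factory=list)
    randomizations: int = 200
    run_stability: bool = True
    hop_cap: int = 3
    active_tol: float = 1e-6
    stability_tol: float = 1e-6
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown configuration keys {sorted(unknown)}")
        return cls(**data)

    def time_windows(self) -> TimeWindows:
        if self.windows is None:
            return DEFAULT_WINDOWS
        return TimeWindows(
            names=tuple(self.windows),
            members=tuple(frozenset(v) for v in self.windows.values()),
        )

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full inference pipeline and write all output tables.

    Returns the run manifest (also written to ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- expression preparation
    matrix = tio.read_expression_tsv(config.expression)
    used = set(config.used_times) if config.used_times else None
    stats = compute_gene_stats(matrix, used_times=used, pseudocount=config.pseudocount)
    filtered = filter_genes(stats, matrix, used_times=used)
    grouping = assign_time_groups(stats, windows=config.time_windows())
    tio.write_stats_tsv(stats, grouping, out / "stats.tsv")

    # --- network assembly (+ knockout)
    records = tio.read_interactions_tsv(config.interactions)
    rename = (
        tio.read_node_rename_tsv(config.node_rename) if config.node_rename else None
    )
    network = build_network(scale_scores(records), node_rename=rename)
    if config.knockout:
        network = apply_knockout(network, config.knockout)
        grouping.assignment = {
            g: w for g, w in grouping.assignment.items() if g not in set(config.knockout)
        }
        grouping.counts = {}
        grouping.__post_init__()
    tio.write_network_tsv(network, out / "network.tsv")

    # --- solve (fixed kappas or sweep)
    sweep_info = None
    if config.sweep:
        result = sweep_kappa(
            network, grouping, stats, mode=config.mode, epsilon=config.epsilon
        )
        solution = result.solution
        kappa1, kappa2 = result.kappa1, result.kappa2
        sweep_info = {"table": result.table, "meets_cap": result.meets_cap}
    else:
        problem = build_problem(
            network,
            grouping,
            stats,
            kappa1=config.kappa1,
            kappa2=config.kappa2,
            mode=config.mode,
            epsilon=config.epsilon,
        )
        solution = solve(problem, active_tol=config.active_tol)
        kappa1, kappa2 = config.kappa1, config.kappa2
    tio.write_arc_table(solution, out / "arcs.tsv")

    # --- significance
    significance = None
    if config.randomizations > 0:
        significance = randomization_pvalues(
            network,
            grouping,
            stats,
            solution,
            R=config.randomizations,
            seed=config.seed,
        )
        tio.write_significance_tsv(significance, out / "significance.tsv")
    tio.write_node_table(solution, out / "nodes.tsv", significance=significance)

    # --- stability
    stability_summary = None
    if config.run_stability:
        report = stability_analysis(solution, tolerance=config.stability_tol)
        tio.write_stability_tsv(report, out / "stability.tsv")
        stability_summary = {
            "unchanged_arc_fraction": report.unchanged_arc_fraction,
            "unchanged_node_fraction": report.unchanged_node_fraction,
            "n_solves": report.n_solves,
        }

    # --- paths
    lengths = opsahl_lengths(solution)
    path_set = shortest_paths_between_stages(
        solution, lengths, hop_cap=config.hop_cap
    )
    tio.write_paths_tsv(path_set, out / "paths.tsv")

    manifest = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_genes_filtered": len(filtered),
        "group_counts": grouping.counts,
        "n_network_nodes": len(network.nodes),
        "n_network_arcs": network.n_arcs,
        "kappa1": kappa1,
        "kappa2": kappa2,
        "mode": config.mode,
        "objective": solution.objective,
        "solver": "scipy-highs",
        "status": solution.status,
        "total_flow": solution.outflow_source,
        "n_active_arcs": len(solution.active_arcs()),
        "n_paths": len(path_set),
        "sweep": sweep_info,
        "stability": stability_summary,
    }
    tio.write_manifest(manifest, out / "manifest.json")
    return manifest
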