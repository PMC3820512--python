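"""Time-course expression handling: fold-change statistics, filtering and
stage assignment.

A gene × time abundance matrix (fpkm-like units, time 0 required) is turned
into per-gene statistics — the maximum absolute log2 fold change ``F_i``
relative to the unstimulated baseline and the mean abundance ``e_bar_i`` —
which parameterize the capacities of the flow problem. Genes passing the
expression filters are partitioned into three response stages according to
the time window in which their fold change peaks:

* T1 (initial response, default 0.5–1 h) — flow sources,
* T2 (intermediate regulators, default 2–4 h) — mandatory transit nodes,
* T3 (late effectors, default 6–8 h) — flow targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InputError

__all__ = [
    "ExpressionMatrix",
    "GeneStats",
    "TimeWindows",
    "TimeGrouping",
    "DEFAULT_WINDOWS",
    "compute_gene_stats",
    "filter_genes",
    "assign_time_groups",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene × time abundance table with a time-0 baseline column.

    Parameters
    ----------
    gene_ids : tuple of str
        Unique gene identifiers (opaque, case-sensitive).
    times : tuple of float
        Sampling times in hours, strictly increasing, must include 0.
    values : numpy.ndarray
        Non-negative abundances, shape ``(len(gene_ids), len(times))``.
    """

    gene_ids: tuple[str, ...]
    times: tuple[float, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InputError("duplicate gene identifiers in expression matrix")
        if 0.0 not in self.times:
            raise ConfigError("expression matrix must include time 0 (baseline)")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise InputError("time points must be strictly increasing")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.gene_ids), len(self.times)):
            raise InputError(
                f"value shape {vals.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.times)} times"
            )
        if np.any(vals < 0):
            raise InputError("negative abundance in expression matrix")
        object.__setattr__(self, "values", vals)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def time_index(self, t: float) -> int:
        try:
            return self.times.index(t)
        except ValueError:
            raise ConfigError(f"time point {t} not present in matrix") from None

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class GeneStats:
    """Per-gene summary used to parameterize flow capacities.

    ``F_i`` is the maximum absolute log2 fold change over the used time
    points relative to time 0; ``e_bar_i`` the mean abundance over the used
    time points plus the baseline.
    """

    gene_id: str
    F_i: float
    e_bar_i: float
    per_time_fc: dict[float, float]
    passes_filters: bool = False


@dataclass(frozen=True)
class TimeWindows:
    """Ordered named time windows; defaults follow the three-stage design."""

    names: tuple[str, ...]
    members: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.members):
            raise ConfigError("window names and member sets differ in length")
        seen: set = set()
        for m in self.members:
            if seen & m:
                raise ConfigError("time windows must be disjoint")
            seen |= m

    def window_of(self, t: float) -> str | None:
        for name, mem in zip(self.names, self.members):
            if t in mem:
                return name
        return None

    def covers(self, times) -> bool:
        covered: set = set()
        for m in self.members:
            covered |= m
        return set(times) <= covered


DEFAULT_WINDOWS = TimeWindows(
    names=("T1", "T2", "T3"),
    members=(frozenset({0.5, 1.0}), frozenset({2.0, 3.0, 4.0}), frozenset({6.0, 8.0})),
)


@dataclass
class TimeGrouping:
    """Stage assignment of filtered genes.

    ``assignment`` maps each gene to the window containing the time of its
    maximal absolute fold change; ``counts`` gives group sizes. Genes in one
    group are disjoint from the others (a partition of the filtered set).
    """

    windows: TimeWindows
    assignment: dict[str, str]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {name: 0 for name in self.windows.names}
            for g, w in self.assignment.items():
                self.counts[w] += 1

    def genes_in(self, window: str) -> list[str]:
        return sorted(g for g, w in self.assignment.items() if w == window)

    @property
    def n_genes(self) -> int:
        return len(self.assignment)


def compute_gene_stats(
    matrix: ExpressionMatrix,
    used_times: set[float] | None = None,
    pseudocount: float = 1.0,
    log_base: float = 2.0,
) -> list[GeneStats]:
    """Per-gene fold-change statistics relative to the time-0 baseline.

    ``per_time_fc[j] = |log((e_ij + c) / (e_i0 + c))|`` (log base
    configurable, default 2) for each used time ``j``; ``F_i`` is their
    maximum and ``e_bar_i`` the mean abundance over the used times plus
    time 0. A pseudocount ``c > 0`` keeps ratios finite for silent genes;
    ``c = 0`` is permitted for exact checks on strictly positive data.
    """
    if pseudocount < 0:
        raise ConfigError("pseudocount must be >= 0")
    if used_times is None:
        used_times = {t for t in matrix.times if t != 0.0}
    used = sorted(used_times)
    if not used:
        raise ConfigError("used_times must contain at least one non-zero time")
    if 0.0 in used_times:
        raise ConfigError("used_times must exclude time 0 (the baseline)")
    if not set(used) <= set(matrix.times):
        raise ConfigError("used_times must be a subset of the matrix times")

    log_div = math.log(log_base)
    idx0 = matrix.time_index(0.0)
    idxs = [matrix.time_index(t) for t in used]
    out: list[GeneStats] = []
    for gi, gene in enumerate(matrix.gene_ids):
        row = matrix.values[gi]
        e0 = row[idx0] + pseudocount
        fc: dict[float, float] = {}
        for t, j in zip(used, idxs):
            ej = row[j] + pseudocount
            if e0 == 0.0 or ej == 0.0:
                # only reachable with pseudocount 0 and a zero abundance
                fc[t] = math.inf if ej != e0 else 0.0
            else:
                fc[t] = abs(math.log(ej / e0) / log_div)
        f_max = max(fc.values())
        e_bar = float(np.mean([row[idx0]] + [row[j] for j in idxs]))
        out.append(GeneStats(gene, f_max, e_bar, fc))
    return out


def filter_genes(
    stats: list[GeneStats],
    matrix: ExpressionMatrix,
    used_times: set[float] | None = None,
    min_abundance: float = 2.0,
    abundance_fraction: float = 0.5,
    high_abundance: float = 10.0,
    high_abundance_points: int = 2,
    min_log_fc: float = 1.0,
) -> set[str]:
    """Genes passing the three expression filters.

    1. abundance ≥ 2 fpkm at ≥ 50% of the considered time points
       (baseline included),
    2. abundance ≥ 10 fpkm at ≥ 2 time points,
    3. fold change > 2-fold at ≥ 1 time point (``F_i > 1`` in log2).

    Sets ``passes_filters`` on each GeneStats as a side effect and returns
    the passing gene set. Thresholds are configurable; the defaults are the
    published ones.
    """
    if used_times is None:
        used_times = set(next(iter(stats)).per_time_fc) if stats else set()
    cols = [matrix.time_index(0.0)] + [matrix.time_index(t) for t in sorted(used_times)]
    survivors: set[str] = set()
    for st in stats:
        row = matrix.row(st.gene_id)[cols]
        ok_abund = np.sum(row >= min_abundance) >= abundance_fraction * len(cols)
        ok_high = np.sum(row >= high_abundance) >= high_abundance_points
        ok_fc = st.F_i > min_log_fc
        st.passes_filters = bool(ok_abund and ok_high and ok_fc)
        if st.passes_filters:
            survivors.add(st.gene_id)
    return survivors


def assign_time_groups(
    stats: list[GeneStats],
    windows: TimeWindows = DEFAULT_WINDOWS,
    filtered: set[str] | None = None,
) -> TimeGrouping:
    """Assign each filtered gene to the window of its peak fold change.

    The argmax time of ``per_time_fc`` decides the window; exact ties are
    broken toward the earliest time point, biasing assignment to the
    earliest window consistent with the causal ordering of a response.
    """
    assignment: dict[str, str] = {}
    for st in stats:
        if filtered is not None and st.gene_id not in filtered:
            continue
        if filtered is None and not st.passes_filters:
            continue
        # earliest time wins ties -> iterate in time order, strict improvement
        best_t, best_fc = None, -1.0
        for t in sorted(st.per_time_fc):
            if st.per_time_fc[t] > best_fc:
                best_t, best_fc = t, st.per_time_fc[t]
        win = windows.window_of(best_t)
        if win is None:
            raise ConfigError(
                f"gene {st.gene_id!r} peaks at time {best_t} which lies in no window"
            )
        assignment[st.gene_id] = win
    return TimeGrouping(windows=windows, assignment=assignment)
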