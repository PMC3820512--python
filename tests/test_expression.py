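"""Fold-change statistics, expression filters and stage assignment."""

import math

import numpy as np
import pytest

from tcflow.errors import ConfigError, InputError
from tcflow.expression import (
    DEFAULT_WINDOWS,
    ExpressionMatrix,
    TimeWindows,
    assign_time_groups,
    compute_gene_stats,
    filter_genes,
)

TIMES = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)


def matrix_of(rows: dict[str, list[float]]) -> ExpressionMatrix:
    return ExpressionMatrix(
        gene_ids=tuple(rows),
        times=TIMES,
        values=np.array(list(rows.values()), dtype=float),
    )


class TestGeneStats:
    @pytest.mark.parametrize(
        "profile,pseudocount,expected_F",
        [
            # doubling at one time point, pseudocount off
            ([10, 20, 10, 10, 10, 10, 10, 10], 0.0, 1.0),
            # constant profile
            ([7, 7, 7, 7, 7, 7, 7, 7], 1.0, 0.0),
            # silent baseline rescued by the pseudocount: |log2(32/1)| = 5
            ([0, 31, 0, 0, 0, 0, 0, 0], 1.0, 5.0),
            # symmetric down-regulation counts through the absolute value
            ([16, 4, 16, 16, 16, 16, 16, 16], 0.0, 2.0),
        ],
    )
    def test_max_abs_log2_fold_change(self, profile, pseudocount, expected_F):
        m = matrix_of({"g": profile})
        (st,) = compute_gene_stats(m, pseudocount=pseudocount)
        assert st.F_i == pytest.approx(expected_F, abs=1e-12)

    def test_mean_abundance_includes_baseline(self):
        m = matrix_of({"g": [8, 1, 1, 1, 1, 1, 1, 1]})
        (st,) = compute_gene_stats(m)
        assert st.e_bar_i == pytest.approx((8 + 7) / 8)

    def test_per_time_fc_keys_are_used_times(self):
        m = matrix_of({"g": [1] * 8})
        (st,) = compute_gene_stats(m, used_times={0.5, 1.0})
        assert set(st.per_time_fc) == {0.5, 1.0}

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(5, 500, size=8)
        m1 = matrix_of({"g": list(base)})
        m2 = matrix_of({"g": list(base * 37.0)})
        (s1,) = compute_gene_stats(m1, pseudocount=0.0)
        (s2,) = compute_gene_stats(m2, pseudocount=0.0)
        assert s1.F_i == pytest.approx(s2.F_i, rel=1e-12)
        # with a pseudocount the change is negligible for abundances >> 1
        (s3,) = compute_gene_stats(m2, pseudocount=1.0)
        assert s3.F_i == pytest.approx(s1.F_i, abs=0.05)

    def test_used_times_must_exclude_baseline(self):
        m = matrix_of({"g": [1] * 8})
        with pytest.raises(ConfigError):
            compute_gene_stats(m, used_times={0.0, 1.0})

    def test_errors(self):
        with pytest.raises(ConfigError):
            ExpressionMatrix(("g",), (1.0, 2.0), np.ones((1, 2)))
        with pytest.raises(InputError):
            ExpressionMatrix(("g",), TIMES, -np.ones((1, 8)))
        with pytest.raises(InputError):
            ExpressionMatrix(("g", "g"), TIMES, np.ones((2, 8)))


class TestFilters:
    def test_hand_computed_survivor_set(self):
        m = matrix_of(
            {
                # 15 fpkm everywhere, one 64-fpkm spike: passes all three
                "induced": [15, 15, 64, 15, 15, 15, 15, 15],
                # all 1 fpkm: fails both abundance criteria
                "silent": [1, 1, 1, 1, 1, 1, 1, 1],
                # abundant but flat: fails only the fold-change criterion
                "flat": [12, 12, 12, 12, 12, 12, 12, 12],
            }
        )
        stats = compute_gene_stats(m)
        assert filter_genes(stats, m) == {"induced"}
        by_id = {s.gene_id: s for s in stats}
        assert by_id["flat"].F_i == 0.0
        assert not by_id["flat"].passes_filters

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        m = matrix_of({f"g{i}": list(rng.uniform(0, 40, 8)) for i in range(40)})
        stats = compute_gene_stats(m)
        base = filter_genes(stats, m)
        relaxed = filter_genes(
            stats, m, min_abundance=1.0, high_abundance=5.0, min_log_fc=0.5
        )
        assert base <= relaxed

    def test_empty_matrix(self):
        m = ExpressionMatrix((), TIMES, np.empty((0, 8)))
        assert filter_genes(compute_gene_stats(m), m) == set()


class TestStageAssignment:
    def _stats(self, profile):
        m = matrix_of({"g": profile})
        stats = compute_gene_stats(m)
        stats[0].passes_filters = True
        return stats

    @pytest.mark.parametrize(
        "profile,window",
        [
            ([10, 10, 10, 10, 90, 10, 10, 10], "T2"),  # peak at 3 h
            ([10, 90, 10, 10, 10, 10, 10, 10], "T1"),  # peak at 0.5 h
            ([10, 10, 10, 10, 10, 10, 10, 90], "T3"),  # peak at 8 h
            ([10, 10, 90, 10, 10, 10, 10, 90], "T1"),  # 1 h / 8 h tie -> earliest
        ],
    )
    def test_assignment(self, profile, window):
        grouping = assign_time_groups(self._stats(profile))
        assert grouping.assignment["g"] == window

    def test_partition_property(self, study_bundle):
        g = study_bundle.grouping
        assert sum(g.counts.values()) == g.n_genes == len(study_bundle.filtered)
        t1, t2, t3 = (set(g.genes_in(w)) for w in ("T1", "T2", "T3"))
        assert not (t1 & t2 or t1 & t3 or t2 & t3)
        assert t1 | t2 | t3 == study_bundle.filtered

    def test_uncovered_peak_is_config_error(self):
        windows = TimeWindows(names=("T1", "T2"), members=(frozenset({0.5}), frozenset({1.0})))
        with pytest.raises(ConfigError):
            assign_time_groups(self._stats([10, 10, 10, 10, 90, 10, 10, 10]), windows)

    def test_disjoint_windows_enforced(self):
        with pytest.raises(ConfigError):
            TimeWindows(names=("a", "b"), members=(frozenset({1.0}), frozenset({1.0})))
        assert DEFAULT_WINDOWS.covers({0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0})
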