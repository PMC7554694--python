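"""Tier assignment, presence partitioning, the tiered caller and the
end-to-end differential-expression analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spcount import (
    DEPRecord, TierRule, TierRuleSet,
    assign_tier, call_dep, classify_presence, partition_summary,
    records_to_frame, run_dep_analysis, write_results,
)
from spcount.dep import test_differential as differential_p
from spcount.dep import ContractError, InsufficientReplicatesError
from tests.conftest import make_matrix

# Hand-written truth table for the published tier grid: mean SpC value -> tier
TIER_TRUTH = [
    (0.0, "below_detection"), (1.0, "below_detection"), (1.69, "below_detection"),
    (1.7, "very_low"), (5.0, "very_low"), (7.0, "very_low"), (7.99, "very_low"),
    (8.0, "low"), (15.0, "low"), (19.0, "low"), (19.99, "low"),
    (20.0, "medium"), (79.0, "medium"), (79.99, "medium"),
    (80.0, "high"), (100.0, "high"), (1e6, "high"),
]


class TestAssignTier:
    @pytest.mark.parametrize("spc,expected", TIER_TRUTH)
    def test_boundary_grid(self, spc, expected):
        assert assign_tier(spc) == expected

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=0, max_value=1e7, allow_nan=False))
    def test_totality(self, spc):
        """Every non-negative mean SpC maps to exactly one tier."""
        assert assign_tier(spc) in {
            "below_detection", "very_low", "low", "medium", "high"}

    def test_non_contiguous_rules_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            TierRuleSet(tiers=(
                TierRule("a", 1.7, 8.0, 0.01, 2.0, 0.5),
                TierRule("b", 9.0, math.inf, 0.05, 2.0, 0.5),
            ))


class TestClassifyPresence:
    @pytest.mark.parametrize("t,r,expected", [
        (5.0, 0.0, "test_only"),
        (0.0, 5.0, "reference_only"),
        (5.0, 5.0, "both"),
        (1.0, 0.0, "neither"),
        (0.0, 0.0, "neither"),
        (1.7, 0.0, "test_only"),  # detection floor is inclusive
        (5.0, 0.5, "both"),       # trace in ref blocks a unique call
    ])
    def test_examples(self, t, r, expected):
        assert classify_presence(t, r) == expected

    @pytest.mark.parametrize("thr", [0.5, 1.0, 1.7, 3.0])
    def test_threshold_sweep(self, thr):
        """A lone positive mean below the floor is 'neither'; at/above, unique."""
        below, above = thr * 0.99, thr
        assert classify_presence(below, 0.0, detection_threshold=thr) == "neither"
        assert classify_presence(above, 0.0, detection_threshold=thr) == "test_only"


class TestTestDifferential:
    def test_identical_vectors_maximal_p(self):
        v = np.array([0.01, 0.01, 0.01])
        assert differential_p(v, v) >= 0.99

    def test_separated_groups_match_independent_welch(self):
        rng = np.random.default_rng(7)
        a = 0.001 * (1 + 1e-3 * rng.standard_normal(3))
        b = 0.01 * (1 + 1e-3 * rng.standard_normal(3))
        p = differential_p(a, b, pseudocount=1e-6)
        assert p < 1e-3
        # independent route: statsmodels Welch t on the same transform
        from statsmodels.stats.weightstats import ttest_ind
        p_ref = ttest_ind(np.log(a + 1e-6), np.log(b + 1e-6),
                          usevar="unequal")[1]
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_group_swap_symmetry(self):
        a, b = np.array([0.1, 0.2, 0.15]), np.array([0.3, 0.25, 0.4])
        assert differential_p(a, b) == pytest.approx(differential_p(b, a))

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            differential_p([0.1], [0.2, 0.3])

    def test_fisher_pooled_alternative(self):
        from scipy.stats import fisher_exact
        p = differential_p([], [], method="fisher_pooled",
                              pooled_counts=(30, 1000, 5, 1000))
        expected = fisher_exact([[30, 970], [5, 995]])[1]
        assert p == pytest.approx(expected)


def brute_force_call(tier, ratio, p):
    """Independent restatement of the published tier thresholds."""
    thresholds = {
        "very_low": (0.001, 2.5, 0.4),
        "low": (0.01, 2.5, 0.4),
        "medium": (0.05, 2.0, 0.5),
        "high": (0.05, 1.5, 0.67),
    }
    p_max, over_min, under_max = thresholds[tier]
    if p > p_max:
        return "unchanged"
    if ratio >= over_min:
        return "overexpressed"
    if ratio <= under_max:
        return "underexpressed"
    return "unchanged"


RATIO_GRID = [0.3, 0.4, 0.5, 0.67, 1.0, 1.5, 2.0, 2.5, 3.0]
P_GRID = [1e-4, 1e-3, 5e-3, 1e-2, 0.04, 0.05, 0.1]


class TestCallDep:
    @pytest.mark.parametrize("tier,ratio,p,expected", [
        ("very_low", 2.5, 0.0005, "overexpressed"),
        ("high", 0.67, 0.04, "underexpressed"),
        ("medium", 1.0, 0.0001, "unchanged"),
        ("very_low", 2.5, 0.005, "unchanged"),  # p passes medium but not very_low
        ("medium", 2.5, 0.005, "overexpressed"),
        ("very_low", 0.4, 0.001, "underexpressed"),  # thresholds inclusive
        ("high", 1.5, 0.05, "overexpressed"),
    ])
    def test_examples(self, tier, ratio, p, expected):
        assert call_dep(tier, "both", ratio, p) == expected

    @pytest.mark.parametrize("tier", ["very_low", "low", "medium", "high"])
    def test_oracle_equivalence_grid(self, tier):
        """call_dep agrees with an independent brute-force restatement on the
        full tier x ratio x p grid."""
        for ratio in RATIO_GRID:
            for p in P_GRID:
                assert call_dep(tier, "both", ratio, p) == \
                    brute_force_call(tier, ratio, p), (tier, ratio, p)

    def test_unique_short_circuits(self):
        assert call_dep("low", "test_only", None, None) == "unique_test"
        assert call_dep("high", "reference_only", None, None) == "unique_reference"

    def test_both_without_ratio_is_contract_error(self):
        with pytest.raises(ContractError):
            call_dep("low", "both", None, 0.5)

    @settings(max_examples=150, deadline=None)
    @given(st.sampled_from(["very_low", "low", "medium", "high"]),
           st.floats(0.001, 0.1), st.floats(1.0, 10.0), st.floats(0.1, 5.0))
    def test_over_monotone_in_ratio(self, tier, p, ratio, bump):
        """For fixed tier and passing p, increasing the ratio never flips
        overexpressed back to unchanged."""
        lo = call_dep(tier, "both", ratio, p)
        hi = call_dep(tier, "both", ratio + bump, p)
        if lo == "overexpressed":
            assert hi == "overexpressed"


class TestRunAnalysis:
    def test_identical_groups_yield_no_deps(self):
        counts = np.tile(np.array([[4], [40], [90]]), (1, 6))
        records, summary = run_dep_analysis(make_matrix(counts), "test", "ref")
        assert (summary.n_over, summary.n_under, summary.n_unique_test,
                summary.n_unique_reference) == (0, 0, 0, 0)
        assert summary.n_common == 3

    def test_single_unique_protein(self):
        records, summary = run_dep_analysis(
            make_matrix([[5, 6, 4, 0, 0, 0]]), "test", "ref")
        assert summary.n_unique_test == 1 and summary.n_dep == 1
        assert records[0].p_value is None and records[0].category == "unique_test"

    def test_tier_from_larger_group_mean(self, small_matrix):
        records, _ = run_dep_analysis(small_matrix, "test", "ref")
        by_acc = {r.accession: r for r in records}
        assert by_acc["P0001"].tier == "medium"  # test mean ~40 dominates

    def test_deterministic_byte_identical_output(self, small_matrix, tmp_path):
        for name in ("a", "b"):
            records, _ = run_dep_analysis(small_matrix, "test", "ref")
            write_results(records_to_frame(records), tmp_path / f"{name}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_too_few_runs_rejected(self):
        m = make_matrix([[1, 2]])  # 1 run per group
        with pytest.raises(InsufficientReplicatesError):
            run_dep_analysis(m, "test", "ref")


def rec(category):
    return DEPRecord("X", "low", 0, 0, 0, 0, None, None, category)


class TestPartitionSummary:
    def test_published_category_counts_total(self):
        records = ([rec("underexpressed")] * 208 + [rec("overexpressed")] * 62
                   + [rec("unique_reference")] * 182 + [rec("unique_test")] * 8)
        s = partition_summary(records)
        assert s.n_dep == 460
        assert (s.n_under, s.n_over, s.n_unique_reference, s.n_unique_test) == \
            (208, 62, 182, 8)

    def test_empty_is_all_zero(self):
        s = partition_summary([])
        assert s.n_dep == 0 and s.n_common == 0 and s.n_below_detection == 0

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.sampled_from([
        "unchanged", "overexpressed", "underexpressed",
        "unique_test", "unique_reference", "below_detection"]), max_size=60))
    def test_accounting_identities(self, categories):
        s = partition_summary([rec(c) for c in categories])
        assert s.n_dep == s.n_over + s.n_under + s.n_unique_test + s.n_unique_reference
        assert s.n_common == s.n_over + s.n_under + s.n_unchanged
        assert s.n_common + s.n_unique_test + s.n_unique_reference + \
            s.n_below_detection == len(categories)
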