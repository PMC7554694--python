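"""Abundance-tiered differential-expression calling on spectral-count data.

Proteins are first binned into abundance tiers by mean spectral count
(very low, low, medium, high); each tier carries its own significance
bound and NSAF-ratio thresholds, so that low-abundance proteins — where
spectral counting is noisiest — must clear a stricter p-value to be
called. Proteins detected in exactly one group are "uniquely expressed"
there and counted as differential without a statistical test. The
remaining (common) proteins are tested for a location difference on
their per-run NSAF values and called overexpressed / underexpressed /
unchanged against the tier's thresholds.

Default tier rules (half-open mean-SpC intervals):

====== ============ ======= ============== ===============
tier   mean SpC     p <=    ratio >= over  ratio <= under
====== ============ ======= ============== ===============
very_low [1.7, 8)   0.001   2.5            0.4
low      [8, 20)    0.01    2.5            0.4
medium   [20, 80)   0.05    2.0            0.5
high     [80, inf)  0.05    1.5            0.67
====== ============ ======= ============== ===============

Mean SpC below 1.7 is below the detection floor. No multiple-testing
correction is applied: the procedure intentionally uses only the tiered
per-test bounds, which is a caveat users should weigh for large matrices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import SpectralCountMatrix
from .nsaf import NSAFTable, compute_nsaf

logger = logging.getLogger(__name__)

DETECTION_THRESHOLD = 1.7

CATEGORIES = (
    "unchanged", "overexpressed", "underexpressed",
    "unique_test", "unique_reference", "below_detection",
)


class ContractError(ValueError):
    """Inconsistent inputs to a caller operation."""


class InsufficientReplicatesError(ValueError):
    """Fewer than two replicate values in a group."""


@dataclass(frozen=True)
class TierRule:
    name: str
    spc_lo: float
    spc_hi: float  # half-open: [spc_lo, spc_hi)
    p_max: float
    over_ratio_min: float
    under_ratio_max: float

    def __post_init__(self) -> None:
        if not (0 < self.p_max <= 1):
            raise ValueError(f"{self.name}: p_max must be in (0, 1]")
        if not (self.over_ratio_min > 1 > self.under_ratio_max > 0):
            raise ValueError(
                f"{self.name}: need over_ratio_min > 1 > under_ratio_max > 0"
            )


@dataclass(frozen=True)
class TierRuleSet:
    """Ordered, contiguous abundance tiers with per-tier DE thresholds."""

    tiers: tuple[TierRule, ...] = (
        TierRule("very_low", 1.7, 8.0, 0.001, 2.5, 0.4),
        TierRule("low", 8.0, 20.0, 0.01, 2.5, 0.4),
        TierRule("medium", 20.0, 80.0, 0.05, 2.0, 0.5),
        TierRule("high", 80.0, math.inf, 0.05, 1.5, 0.67),
    )

    def __post_init__(self) -> None:
        if not self.tiers:
            raise ValueError("at least one tier required")
        for a, b in zip(self.tiers, self.tiers[1:]):
            if a.spc_hi != b.spc_lo:
                raise ValueError(
                    f"tiers {a.name}/{b.name} not contiguous: {a.spc_hi} != {b.spc_lo}"
                )

    @property
    def detection_threshold(self) -> float:
        return self.tiers[0].spc_lo

    def rule(self, name: str) -> TierRule:
        for t in self.tiers:
            if t.name == name:
                return t
        raise KeyError(f"unknown tier {name!r}")


@dataclass
class DEPRecord:
    """Per-protein outcome of the tiered differential-expression call."""

    accession: str
    tier: str  # tier name or "below_detection"
    mean_spc_test: float
    mean_spc_ref: float
    mean_nsaf_test: float
    mean_nsaf_ref: float
    nsaf_ratio: float | None  # test / reference; None when undefined
    p_value: float | None  # defined only for proteins present in both groups
    category: str


@dataclass
class PartitionSummary:
    """Accounting of the presence/DE partition over one analysis."""

    n_common: int = 0
    n_unchanged: int = 0
    n_over: int = 0
    n_under: int = 0
    n_unique_test: int = 0
    n_unique_reference: int = 0
    n_below_detection: int = 0

    @property
    def n_dep(self) -> int:
        return (self.n_over + self.n_under
                + self.n_unique_test + self.n_unique_reference)


def assign_tier(mean_spc: float, rules: TierRuleSet | None = None) -> str:
    """Map a mean spectral count to its abundance tier.

    Total on non-negative inputs: values below the lowest tier edge return
    ``"below_detection"``; tier intervals are half-open ``[lo, hi)``.
    """
    rules = rules or TierRuleSet()
    if mean_spc < rules.detection_threshold:
        return "below_detection"
    for t in rules.tiers:
        if t.spc_lo <= mean_spc < t.spc_hi:
            return t.name
    return rules.tiers[-1].name  # mean_spc == inf


def classify_presence(
    mean_spc_test: float,
    mean_spc_ref: float,
    detection_threshold: float = DETECTION_THRESHOLD,
) -> str:
    """Partition a protein by which groups detect it.

    A group *has* the protein when its mean SpC is at or above the
    detection floor. A unique call additionally requires strict absence
    (mean SpC exactly 0) in the other group, reading "uniquely expressed"
    literally. Returns one of ``both``, ``test_only``, ``reference_only``,
    ``neither``.
    """
    has_test = mean_spc_test >= detection_threshold
    has_ref = mean_spc_ref >= detection_threshold
    if has_test and has_ref:
        return "both"
    if has_test and mean_spc_ref == 0:
        return "test_only"
    if has_ref and mean_spc_test == 0:
        return "reference_only"
    if has_test or has_ref:
        # one group detected, the other has a trace (0 < SpC < floor):
        # not unique by the strict-absence rule, and not a two-group
        # comparison either; treat as both so the protein is still tested.
        return "both"
    return "neither"


def test_differential(
    nsaf_test: np.ndarray,
    nsaf_ref: np.ndarray,
    method: str = "welch_log_nsaf",
    pseudocount: float | None = None,
    pooled_counts: tuple[int, int, int, int] | None = None,
) -> float:
    """Two-sided p-value for a group difference in protein abundance.

    ``welch_log_nsaf`` (default) applies Welch's unequal-variance t-test to
    log(NSAF + pseudocount) replicate values; the pseudocount guards zeros
    and defaults to half the smallest nonzero value seen. The alternative
    ``fisher_pooled`` ignores the NSAF vectors and runs Fisher's exact test
    on pooled counts (protein vs rest of run, per group), supplied as
    ``(spc_test, total_test, spc_ref, total_ref)``.

    Symmetric in the two groups.
    """
    nsaf_test = np.asarray(nsaf_test, dtype=float)
    nsaf_ref = np.asarray(nsaf_ref, dtype=float)
    if method == "fisher_pooled":
        if pooled_counts is None:
            raise ContractError("fisher_pooled requires pooled_counts")
        a, ta, b, tb = pooled_counts
        table = [[a, ta - a], [b, tb - b]]
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method != "welch_log_nsaf":
        raise ValueError(f"unknown test method {method!r}")
    if len(nsaf_test) < 2 or len(nsaf_ref) < 2:
        raise InsufficientReplicatesError(
            "Welch's t-test needs >= 2 replicates per group"
        )
    if pseudocount is None:
        nonzero = np.concatenate([nsaf_test, nsaf_ref])
        nonzero = nonzero[nonzero > 0]
        pseudocount = nonzero.min() / 2 if len(nonzero) else 1.0
    x = np.log(nsaf_test + pseudocount)
    y = np.log(nsaf_ref + pseudocount)
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    p = stats.ttest_ind(x, y, equal_var=False).pvalue
    return float(min(1.0, p))


def call_dep(
    tier: str,
    presence: str,
    nsaf_ratio: float | None,
    p_value: float | None,
    rules: TierRuleSet | None = None,
) -> str:
    """Categorize one protein given its tier, presence state, NSAF ratio
    (test/reference) and p-value.

    Unique presence short-circuits to the unique category. Otherwise the
    protein is overexpressed iff p <= p_max(tier) and ratio >= the tier's
    over threshold, underexpressed iff p <= p_max(tier) and ratio <= the
    tier's under threshold, else unchanged. All thresholds are inclusive.
    """
    if presence == "test_only":
        return "unique_test"
    if presence == "reference_only":
        return "unique_reference"
    if presence == "neither" or tier == "below_detection":
        return "below_detection"
    if presence != "both":
        raise ContractError(f"unknown presence state {presence!r}")
    if nsaf_ratio is None or p_value is None:
        raise ContractError("presence 'both' requires a defined ratio and p-value")
    rules = rules or TierRuleSet()
    rule = rules.rule(tier)
    if p_value <= rule.p_max:
        if nsaf_ratio >= rule.over_ratio_min:
            return "overexpressed"
        if nsaf_ratio <= rule.under_ratio_max:
            return "underexpressed"
    return "unchanged"


def partition_summary(records: list[DEPRecord]) -> PartitionSummary:
    """Tally DEP records into the presence/DE partition.

    Satisfies ``n_dep = n_over + n_under + n_unique_test +
    n_unique_reference`` and ``n_over + n_under + n_unchanged = n_common``.
    """
    s = PartitionSummary()
    for r in records:
        if r.category == "unchanged":
            s.n_unchanged += 1
        elif r.category == "overexpressed":
            s.n_over += 1
        elif r.category == "underexpressed":
            s.n_under += 1
        elif r.category == "unique_test":
            s.n_unique_test += 1
        elif r.category == "unique_reference":
            s.n_unique_reference += 1
        elif r.category == "below_detection":
            s.n_below_detection += 1
        else:
            raise ContractError(f"unknown category {r.category!r}")
    s.n_common = s.n_unchanged + s.n_over + s.n_under
    return s


def run_dep_analysis(
    matrix: SpectralCountMatrix,
    test_group: str,
    ref_group: str,
    rules: TierRuleSet | None = None,
    method: str = "welch_log_nsaf",
    nsaf_table: NSAFTable | None = None,
) -> tuple[list[DEPRecord], PartitionSummary]:
    """Run the full tiered DEP procedure for test vs reference group.

    Pipeline: NSAF quantification -> tier assignment from the larger of
    the two group mean SpCs -> presence partition -> per-protein test on
    NSAF replicates -> threshold call. Deterministic for a fixed input.
    """
    rules = rules or TierRuleSet()
    matrix.require_two_groups()
    for g in (test_group, ref_group):
        if len(matrix.run_indices(g)) < 2:
            raise InsufficientReplicatesError(f"group {g!r} has < 2 runs")
    nt = nsaf_table if nsaf_table is not None else compute_nsaf(matrix)

    idx_test = matrix.run_indices(test_group)
    idx_ref = matrix.run_indices(ref_group)
    ok_runs = ~np.isnan(nt.nsaf).all(axis=0)
    idx_test_ok = idx_test[ok_runs[idx_test]]
    idx_ref_ok = idx_ref[ok_runs[idx_ref]]

    mean_spc_test = nt.group_mean_spc[test_group]
    mean_spc_ref = nt.group_mean_spc[ref_group]
    mean_nsaf_test = nt.group_mean_nsaf[test_group]
    mean_nsaf_ref = nt.group_mean_nsaf[ref_group]

    # global pseudocount: half the smallest nonzero NSAF in the matrix
    nonzero = nt.nsaf[np.isfinite(nt.nsaf) & (nt.nsaf > 0)]
    pseudocount = float(nonzero.min() / 2) if len(nonzero) else 1.0

    total_test = int(matrix.counts[:, idx_test].sum())
    total_ref = int(matrix.counts[:, idx_ref].sum())

    records: list[DEPRecord] = []
    for i, acc in enumerate(matrix.accessions):
        mst, msr = float(mean_spc_test[i]), float(mean_spc_ref[i])
        tier = assign_tier(max(mst, msr), rules)
        presence = classify_presence(mst, msr, rules.detection_threshold)
        ratio: float | None = None
        p: float | None = None
        if presence == "both":
            a, b = float(mean_nsaf_test[i]), float(mean_nsaf_ref[i])
            ratio = math.inf if b == 0 else a / b
            if method == "fisher_pooled":
                p = test_differential(
                    [], [], method=method,
                    pooled_counts=(
                        int(matrix.counts[i, idx_test].sum()), total_test,
                        int(matrix.counts[i, idx_ref].sum()), total_ref,
                    ),
                )
            else:
                p = test_differential(
                    nt.nsaf[i, idx_test_ok], nt.nsaf[i, idx_ref_ok],
                    method=method, pseudocount=pseudocount,
                )
        category = call_dep(tier, presence, ratio, p, rules)
        records.append(DEPRecord(
            accession=acc, tier=tier,
            mean_spc_test=mst, mean_spc_ref=msr,
            mean_nsaf_test=float(mean_nsaf_test[i]),
            mean_nsaf_ref=float(mean_nsaf_ref[i]),
            nsaf_ratio=ratio, p_value=p, category=category,
        ))
    summary = partition_summary(records)
    logger.info(
        "DEP analysis %s vs %s: %d proteins, %d DEPs (%d over, %d under, "
        "%d unique-%s, %d unique-%s)",
        test_group, ref_group, len(records), summary.n_dep, summary.n_over,
        summary.n_under, summary.n_unique_test, test_group,
        summary.n_unique_reference, ref_group,
    )
    return records, summary


def records_to_frame(records: list[DEPRecord]):
    """DEP records as a pandas DataFrame in the fixed output column order."""
    import pandas as pd

    return pd.DataFrame([
        {
            "accession": r.accession, "tier": r.tier,
            "mean_spc_test": r.mean_spc_test, "mean_spc_ref": r.mean_spc_ref,
            "mean_nsaf_test": r.mean_nsaf_test, "mean_nsaf_ref": r.mean_nsaf_ref,
            "nsaf_ratio": r.nsaf_ratio, "p_value": r.p_value,
            "category": r.category,
        }
        for r in records
    ], columns=[
        "accession", "tier", "mean_spc_test", "mean_spc_ref",
        "mean_nsaf_test", "mean_nsaf_ref", "nsaf_ratio", "p_value", "category",
    ])
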