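# Methods

## Scope and model

`spcount` implements a comparative spectral-counting workflow for
two-group label-free proteomics. The observable is the spectral count
SpC — the number of MS/MS spectra matched to a protein in a run — which
grows with protein abundance but also with protein length and run depth.
NSAF corrects both: length-normalize, then normalize each run to sum
to 1. All downstream inference (effect sizes as NSAF ratios, tests on
NSAF replicates) happens on this scale; mean SpC is kept alongside as
the abundance measure that drives tier assignment.

The pipeline starts from a count matrix. Peptide-to-protein inference,
search-engine scoring and raw spectra are out of scope: those belong to
the search/aggregation software that produced the export.

## The tiered caller

Spectral counts are noisy in a strongly abundance-dependent way, so a
single global threshold either floods the low-abundance range with false
calls or starves the high-abundance range of power. The tiered rule set
addresses this by binning proteins on mean SpC and attaching stricter
p-bounds and larger ratio thresholds to lower tiers (see the README
table). Decisions taken where the published procedure is underspecified:

- **Bin boundaries.** The printed bins ("1.7–7", "8–19", "20–79", ">80")
  leave gaps (7–8, 79–80) that fractional means can fall into. We use
  contiguous half-open intervals [1.7, 8), [8, 20), [20, 80), [80, ∞):
  total on fractional means and in agreement with every printed integer.
- **Tier statistic.** A protein is tiered by the **maximum** of its two
  group-mean SpCs: a protein well measured in either group should be
  judged at that evidence level.
- **Mean, not total.** The fractional bin edge 1.7 only makes sense for
  a per-group mean over runs, so tiers are assigned from mean SpC.
- **Statistical test.** No test is prescribed by the tier rules, only
  p-bounds. The default is Welch's unequal-variance t-test on
  log(NSAF + p₀), with p₀ = half the smallest nonzero NSAF in the matrix
  — a variance-stabilizing transform that keeps zeros finite without
  dominating the scale. The choice is isolated behind
  `test_differential`, and Fisher's exact test on pooled counts
  (protein vs rest of run, summed per group) is available via
  `method="fisher_pooled"` for designs with too few runs for a t-test to
  be meaningful. With both groups constant and equal the t-test is
  degenerate; we return p = 1 (no evidence) rather than NaN.
- **Unique expression.** Read literally as absence: mean SpC ≥ 1.7 in
  one group and exactly 0 in the other. A protein detected in one group
  with a nonzero trace below the floor in the other is *not* unique; it
  is treated as common and tested, so a single stray spectrum cannot be
  promoted to qualitative absence.
- **No multiple-testing correction**, deliberately matching the tiered
  per-test procedure. For matrices with thousands of proteins the
  over/under lists should be read as threshold exceedances, not
  FDR-controlled discoveries; the simulator's null calibration quantifies
  the practical false-call rate (far below the nominal p-bound, because
  the ratio threshold must also be crossed).

Thresholds are inclusive (≤ / ≥ as printed). All tier parameters live in
`TierRuleSet` and can be overridden wholesale from the CLI config.

## Pathway layer

Over-representation uses the hypergeometric upper tail with the universe
defaulting to all proteins detected in the analysis (not the whole
proteome), which avoids inflating enrichment through detection bias; a
custom universe can be supplied. The activation z-score is the additive
form z = (consistent − inconsistent)/√(scoreable): each direction-
annotated set member contributes ±1 according to whether its observed
direction matches the expected-under-activation direction. Uniquely
expressed proteins contribute their sign by default (they are part of
the differential evidence) and can be excluded
(`include_unique_in_z=False`). The activation call uses strict
inequalities — z must exceed 2 or fall below −2; a set scoring exactly
±2 gets no prediction. Sets with no scoreable member get no prediction
rather than z = 0, to keep "no evidence" distinct from "balanced
evidence".

## Synthetic data

The generator emulates a two-group pooled-sample design: 3 runs per
group by default, protein lengths uniform on 100–2000 residues, baseline
expected counts μᵢ log-normal (median 5, σ_log = 1) so that the bulk of
detected proteins fall in the very-low tier and a visible fraction sits
below the detection floor — the right-skewed abundance profile typical
of these experiments. Counts are negative binomial with mean μᵢ·fᵢ,g and
dispersion θ = 5 (variance μ + μ²/θ), capturing between-run biological
and pooling variability that Poisson noise understates. Effects are
multiplicative: f = effect size (default 4) for overexpressed proteins
in the test group, its reciprocal for underexpressed, and 0 in the
absent group of unique proteins. Default DE fractions are 5% over, 15%
under, 1% unique-test, 13% unique-reference, mirroring a design where
underexpression and reference-only presence dominate. One
`numpy.random.default_rng(seed)` drives all randomness.

What the simulator does **not** model: donor pooling before measurement
(runs are sampled independently given μ), peptide-level effects, protein
inference errors, run-depth drift, or correlated proteins. Passing
recovery tests therefore demonstrates the caller's behavior under clean
count noise with known effects — not performance on real data, where
these extra error sources apply.

`evaluate_recovery` reports a per-true-category confusion matrix, pooled
sensitivity and FDR over all DE classes, and unique-protein sensitivity
both overall and restricted to *detectable* unique proteins (realized
present-group mean SpC ≥ 1.7). The restricted figure is the informative
one: a unique protein whose draws never reach the floor is invisible to
any caller.

## Numerical and testing choices

- NSAF normalization is exact to < 1e-9 per run (verified over 1000
  random matrices); zero-total runs are excluded from group means with a
  warning rather than imputed, since their normalization is undefined.
- The hypergeometric tail is checked against exhaustive enumeration of
  all draws for every universe of at most 12 proteins; the tier and
  caller rules are checked against hand-written truth tables and an
  independently coded brute-force restatement over a 252-cell grid.
- Reference recovery figures come from a frozen simulation (500
  proteins, 3 runs/group, effect 4, θ = 5, fractions 5/5/2/2%, seed 42):
  detectable-unique sensitivity 1.000, pooled sensitivity 0.429,
  FDR 0.091; a matched null run yields 0.8% over/under calls. The test
  bands around these values were frozen from that first run. Problem
  sizes in the suite (500-protein recovery runs, 40 null datasets for
  calibration) were chosen to keep the full suite fast while leaving the
  checked bounds meaningful.
- Results TSVs render floats with `%.6g` and missing values as `NA`, so
  identical inputs produce byte-identical outputs and files round-trip
  through the readers.

## Limitations

- Two groups only; no paired or multi-factor designs.
- Power at the very-low tier with 3 replicates per group is intrinsically
  poor (p ≤ 0.001 from a 3-vs-3 t-test requires near-zero within-group
  variance), so pooled sensitivity is dominated by the abundance
  distribution; this is a property of the tiered procedure itself.
- The pathway layer scores user-supplied gene sets and signed
  regulator-target networks; no knowledge base is bundled beyond a toy
  demo, and causal-network algorithms beyond the additive z-score are
  out of scope.
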