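"""Synthetic spectral-count datasets with known ground truth.

The generator emulates a two-group label-free spectral-counting design:
two groups of pooled biological samples, a small number of runs per group
(default 3), counts that are overdispersed relative to Poisson, a strongly
right-skewed abundance distribution so that most proteins sit in the
very-low abundance tier, and a minority of proteins that are truly
over-/underexpressed in the test group or present in only one group.

Count model: protein *i* in run *r* of group *g* draws

    SpC_{i,r} ~ NegativeBinomial(mean = mu_i * f_{i,g}, dispersion = theta)

with mu_i log-normal, f = effect_size (overexpressed in test),
1/effect_size (underexpressed in test), 0 in the absent group of a unique
protein, and 1 otherwise. The negative binomial uses the ecological
(mu, theta) parameterization: variance = mu + mu^2/theta, so larger theta
means closer to Poisson. Pooling of donors is not modelled explicitly;
runs are sampled independently given mu.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .dep import DEPRecord
from .matrix import SpectralCountMatrix

TRUE_CATEGORIES = ("unchanged", "overexpressed", "underexpressed",
                   "unique_test", "unique_reference")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-group spectral-count experiment.

    Defaults mirror the emulated study design: 3 runs per group, a
    log-normal abundance distribution placing the bulk of proteins in the
    very-low tier (median expected SpC ~5), moderate overdispersion, and a
    DEP minority dominated by underexpression and reference-only proteins.
    """

    n_proteins: int = 1200
    n_runs_per_group: int = 3
    length_range: tuple[int, int] = (100, 2000)
    log_mu_mean: float = np.log(5.0)  # log expected SpC of a typical protein
    log_mu_sd: float = 1.0
    dispersion: float = 5.0  # NB theta; var = mu + mu^2/theta
    frac_over: float = 0.05
    frac_under: float = 0.15
    frac_unique_test: float = 0.01
    frac_unique_ref: float = 0.13
    effect_size: float = 4.0
    seed: int = 0
    test_group: str = "cancer"
    ref_group: str = "fertile"

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be positive")
        if self.n_runs_per_group < 2:
            raise ConfigError("n_runs_per_group must be >= 2")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ConfigError("length_range must satisfy 1 <= lo <= hi")
        fracs = (self.frac_over, self.frac_under,
                 self.frac_unique_test, self.frac_unique_ref)
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ConfigError("fractions must be >= 0 and sum to <= 1")
        if self.effect_size <= 1:
            raise ConfigError("effect_size must be > 1")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth attached to a simulated matrix."""

    accessions: list[str]
    categories: list[str]  # one of TRUE_CATEGORIES per protein
    fold_changes: np.ndarray  # multiplicative test-vs-ref effect per protein
    mu: np.ndarray  # baseline expected SpC per protein
    config: SimulationConfig = field(repr=False, default=None)

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in TRUE_CATEGORIES}
        for c in self.categories:
            out[c] += 1
        return out


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial with mean/dispersion parameterization."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = theta / (theta + mean[pos])
        out[pos] = rng.negative_binomial(theta, p)
    return out


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[SpectralCountMatrix, SyntheticTruth]:
    """Draw a synthetic count matrix and its ground truth.

    Reproducible for a fixed seed; all randomness flows through a single
    ``numpy.random.default_rng(config.seed)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins

    accessions = [f"PROT{i:05d}" for i in range(n)]
    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, n)
    mu = rng.lognormal(config.log_mu_mean, config.log_mu_sd, n)

    n_over = round(config.frac_over * n)
    n_under = round(config.frac_under * n)
    n_ut = round(config.frac_unique_test * n)
    n_ur = round(config.frac_unique_ref * n)
    perm = rng.permutation(n)
    categories = np.array(["unchanged"] * n, dtype=object)
    start = 0
    for label, count in (("overexpressed", n_over), ("underexpressed", n_under),
                         ("unique_test", n_ut), ("unique_reference", n_ur)):
        categories[perm[start:start + count]] = label
        start += count

    fold = np.ones(n)
    fold[categories == "overexpressed"] = config.effect_size
    fold[categories == "underexpressed"] = 1.0 / config.effect_size

    mean_test = mu * fold
    mean_ref = mu.copy()
    mean_test[categories == "unique_reference"] = 0.0
    mean_ref[categories == "unique_test"] = 0.0

    k = config.n_runs_per_group
    counts = np.empty((n, 2 * k), dtype=np.int64)
    for r in range(k):
        counts[:, r] = _nb_sample(rng, mean_test, config.dispersion)
    for r in range(k):
        counts[:, k + r] = _nb_sample(rng, mean_ref, config.dispersion)

    run_ids = ([f"{config.test_group}_r{r+1}" for r in range(k)]
               + [f"{config.ref_group}_r{r+1}" for r in range(k)])
    groups = {r: config.test_group for r in run_ids[:k]}
    groups.update({r: config.ref_group for r in run_ids[k:]})

    matrix = SpectralCountMatrix(
        accessions=accessions, lengths=lengths, counts=counts,
        run_ids=run_ids, groups=groups,
    )
    truth = SyntheticTruth(
        accessions=accessions, categories=list(categories),
        fold_changes=fold, mu=mu, config=config,
    )
    return matrix, truth


@dataclass
class RecoveryReport:
    """Confusion matrix and summary rates of truth recovery."""

    confusion: dict[str, dict[str, int]]  # true category -> called -> count
    sensitivity: float  # pooled over+under+unique: called DE and truly DE / truly DE
    fdr: float  # called DE but truly unchanged / called DE
    unique_sensitivity: float  # unique-truth proteins recovered as unique
    unique_sensitivity_detectable: float  # ... among those with mean SpC >= floor
    per_category_sensitivity: dict[str, float]

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate_recovery(
    records: list[DEPRecord],
    truth: SyntheticTruth,
    detection_threshold: float = 1.7,
) -> RecoveryReport:
    """Compare pipeline calls with simulation ground truth.

    Sensitivity and FDR pool the over/under/unique classes: a protein
    counts as recovered when it is called in any DEP category, and as a
    false discovery when called DEP while truly unchanged. Unique
    sensitivity is additionally reported restricted to *detectable* unique
    proteins — those whose realized mean SpC in the present group reaches
    the detection floor, the only ones the caller could possibly see.
    """
    if [r.accession for r in records] != truth.accessions:
        raise ValueError("records and truth cover different protein universes")

    dep_called = {"overexpressed", "underexpressed", "unique_test", "unique_reference"}
    confusion: dict[str, dict[str, int]] = {c: {} for c in TRUE_CATEGORIES}
    true_de = called_true = called_de = called_false = 0
    uniq_total = uniq_hit = uniq_det_total = uniq_det_hit = 0
    cat_total = {c: 0 for c in TRUE_CATEGORIES}
    cat_hit = {c: 0 for c in TRUE_CATEGORIES}

    for rec, true_cat in zip(records, truth.categories):
        confusion[true_cat][rec.category] = confusion[true_cat].get(rec.category, 0) + 1
        is_true_de = true_cat != "unchanged"
        is_called_de = rec.category in dep_called
        cat_total[true_cat] += 1
        if rec.category == true_cat:
            cat_hit[true_cat] += 1
        if is_true_de:
            true_de += 1
            if is_called_de:
                called_true += 1
        if is_called_de:
            called_de += 1
            if not is_true_de:
                called_false += 1
        if true_cat in ("unique_test", "unique_reference"):
            uniq_total += 1
            present_mean = (rec.mean_spc_test if true_cat == "unique_test"
                            else rec.mean_spc_ref)
            hit = rec.category == true_cat
            if hit:
                uniq_hit += 1
            if present_mean >= detection_threshold:
                uniq_det_total += 1
                if hit:
                    uniq_det_hit += 1

    return RecoveryReport(
        confusion=confusion,
        sensitivity=called_true / true_de if true_de else float("nan"),
        fdr=called_false / called_de if called_de else 0.0,
        unique_sensitivity=uniq_hit / uniq_total if uniq_total else float("nan"),
        unique_sensitivity_detectable=(
            uniq_det_hit / uniq_det_total if uniq_det_total else float("nan")
        ),
        per_category_sensitivity={
            c: (cat_hit[c] / cat_total[c] if cat_total[c] else float("nan"))
            for c in TRUE_CATEGORIES
        },
    )
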