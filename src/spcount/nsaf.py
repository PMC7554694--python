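"""Normalized spectral abundance factor (NSAF) quantification.

For protein *i* with sequence length :math:`L_i` and spectral count
:math:`\\mathrm{SpC}_{i,r}` in run *r*, the spectral abundance factor is
:math:`\\mathrm{SAF}_{i,r} = \\mathrm{SpC}_{i,r}/L_i` and

.. math::

    \\mathrm{NSAF}_{i,r} = \\frac{\\mathrm{SpC}_{i,r}/L_i}
                                {\\sum_j \\mathrm{SpC}_{j,r}/L_j}

so NSAF sums to 1 within each run, making runs of different depth
comparable. NSAF is computed per run and group means are arithmetic means
over that group's runs, preserving run-level variability for the
downstream statistical test. Runs with zero total counts have no defined
normalization; they are flagged and excluded from group means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix import SpectralCountMatrix

logger = logging.getLogger(__name__)


@dataclass
class NSAFTable:
    """Per-run NSAF values plus per-group mean NSAF and mean SpC.

    ``nsaf`` has shape (n_proteins, n_runs); columns of all-zero runs are
    NaN and listed in ``zero_total_runs``. ``group_mean_nsaf`` and
    ``group_mean_spc`` map group label -> per-protein vector.
    """

    accessions: list[str]
    run_ids: list[str]
    nsaf: np.ndarray
    group_mean_nsaf: dict[str, np.ndarray]
    group_mean_spc: dict[str, np.ndarray]
    zero_total_runs: list[str]


def compute_nsaf(matrix: SpectralCountMatrix) -> NSAFTable:
    """Compute per-run NSAF and per-group means from a count matrix."""
    if matrix.n_proteins < 1:
        raise ValueError("NSAF needs at least one protein")
    saf = matrix.counts / matrix.lengths[:, None]
    totals = saf.sum(axis=0)
    zero_runs = [r for r, t in zip(matrix.run_ids, totals) if t == 0]
    if zero_runs:
        logger.warning(
            "runs with zero total counts excluded from group means: %s", zero_runs
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        nsaf = np.where(totals > 0, saf / totals, np.nan)

    group_mean_nsaf: dict[str, np.ndarray] = {}
    group_mean_spc: dict[str, np.ndarray] = {}
    for g in matrix.group_labels:
        idx = matrix.run_indices(g)
        ok = idx[totals[idx] > 0]
        if len(ok):
            group_mean_nsaf[g] = nsaf[:, ok].mean(axis=1)
        else:
            group_mean_nsaf[g] = np.full(matrix.n_proteins, np.nan)
        group_mean_spc[g] = matrix.counts[:, idx].mean(axis=1)
    return NSAFTable(
        accessions=list(matrix.accessions),
        run_ids=list(matrix.run_ids),
        nsaf=nsaf,
        group_mean_nsaf=group_mean_nsaf,
        group_mean_spc=group_mean_spc,
        zero_total_runs=zero_runs,
    )


def mean_spc(matrix: SpectralCountMatrix, group: str) -> np.ndarray:
    """Arithmetic mean spectral count over a group's runs, per protein.

    Means may be fractional; abundance-tier bin edges (e.g. 1.7) assume this.
    """
    idx = matrix.run_indices(group)
    return matrix.counts[:, idx].mean(axis=1)
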