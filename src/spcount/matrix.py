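"""Core container for label-free spectral-count data.

A shotgun proteomics experiment quantified by spectral counting reduces to a
proteins x runs matrix of non-negative integers (the number of MS/MS spectra
matched to each protein in each run), plus the protein sequence lengths needed
for length normalization and a mapping from runs to experimental groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MatrixFormatError(ValueError):
    """A count matrix violates its structural contract."""


class DesignError(ValueError):
    """The run -> group design is missing runs or has too few groups."""


@dataclass
class SpectralCountMatrix:
    """Proteins x runs spectral counts with lengths and group labels.

    Parameters
    ----------
    accessions
        Unique protein identifiers (opaque, case-sensitive strings).
    lengths
        Protein sequence length in amino-acid residues, one per protein,
        all >= 1. Used by NSAF to correct for the fact that longer proteins
        yield more tryptic peptides and hence more spectra.
    counts
        Integer array of shape ``(n_proteins, n_runs)``, all >= 0.
    run_ids
        Unique run identifiers, one per column.
    groups
        Mapping run id -> group label; every run must be labelled.
    """

    accessions: list[str]
    lengths: np.ndarray
    counts: np.ndarray
    run_ids: list[str]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths)
        self.counts = np.asarray(self.counts)
        n_prot, n_runs = len(self.accessions), len(self.run_ids)
        if len(set(self.accessions)) != n_prot:
            seen: set[str] = set()
            dup = next(a for a in self.accessions if a in seen or seen.add(a))
            raise MatrixFormatError(f"duplicate accession: {dup!r}")
        if len(set(self.run_ids)) != n_runs:
            raise MatrixFormatError("duplicate run ids")
        if self.counts.shape != (n_prot, n_runs):
            raise MatrixFormatError(
                f"counts shape {self.counts.shape} != ({n_prot}, {n_runs})"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise MatrixFormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise MatrixFormatError("negative spectral counts")
        if self.lengths.shape != (n_prot,):
            raise MatrixFormatError("one length per protein required")
        if n_prot and self.lengths.min() < 1:
            raise MatrixFormatError("protein lengths must be >= 1")
        self.lengths = self.lengths.astype(np.int64)
        missing = [r for r in self.run_ids if r not in self.groups]
        if missing:
            raise DesignError(f"runs missing from design: {missing}")

    @property
    def n_proteins(self) -> int:
        return len(self.accessions)

    @property
    def n_runs(self) -> int:
        return len(self.run_ids)

    @property
    def group_labels(self) -> list[str]:
        """Distinct group labels in order of first appearance over runs."""
        out: list[str] = []
        for r in self.run_ids:
            g = self.groups[r]
            if g not in out:
                out.append(g)
        return out

    def run_indices(self, group: str) -> np.ndarray:
        """Column indices of the runs belonging to *group*."""
        idx = [i for i, r in enumerate(self.run_ids) if self.groups[r] == group]
        if not idx:
            raise KeyError(f"unknown group label: {group!r}")
        return np.asarray(idx)

    def require_two_groups(self) -> None:
        if len(self.group_labels) < 2:
            raise DesignError(
                f"a comparison needs two groups, found {self.group_labels}"
            )
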