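"""Packaged demo fixtures.

``table2_unique_cancer.tsv`` carries the printed identities and abundance
labels (L = low, VL = very low) of the eight sperm proteins detected only
in the cancer group of the emulated study. The companion
``table2_synthetic_counts.tsv`` is a SYNTHETIC count matrix: the study
deposited no raw counts, so these spectral counts were constructed to be
consistent with the printed abundance labels (cancer-only presence, mean
SpC in the labelled tier) with approximate true sequence lengths. The toy
GMT/direction files sketch oxidative-phosphorylation and TCA-cycle sets
for docs and tests; they are not a curated knowledge base.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .io import read_count_matrix
from .matrix import SpectralCountMatrix


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    return Path(resources.files("spcount") / "data" / name)


def load_table2_fixture() -> tuple[SpectralCountMatrix, pd.DataFrame]:
    """Load the unique-in-cancer demo: synthetic count matrix + printed
    metadata (UniProt id, protein name, abundance label)."""
    matrix = read_count_matrix(
        fixture_path("table2_synthetic_counts.tsv"),
        fixture_path("table2_synthetic_design.tsv"),
    )
    meta = pd.read_csv(fixture_path("table2_unique_cancer.tsv"), sep="\t")
    return matrix, meta
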