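"""Readers and writers for every external table the pipeline touches.

Formats are deliberately plain and diffable:

* count matrix — TSV, header ``accession<TAB>length<TAB><run ids...>``
* design — TSV with columns ``run_id``, ``group``
* gene sets — standard GMT (name, description, members...)
* signed directions — TSV sidecar with columns ``set_name``, ``member``,
  ``sign`` (+1 / -1), giving each member's expected expression direction
  when the set or upstream regulator is active
* results — TSV with a fixed per-kind column order and explicit float
  precision so a fixed input always produces a byte-identical file
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import DesignError, MatrixFormatError, SpectralCountMatrix

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


class GMTFormatError(ValueError):
    """A GMT or directions file violates the format contract."""


class GeneSetCollection:
    """Named sets of protein accessions, optionally with signed directions.

    ``directions[(set_name, member)]`` is +1 if the member is expected to go
    up when the set/regulator is active, -1 if down.
    """

    def __init__(
        self,
        sets: dict[str, list[str]] | None = None,
        directions: dict[tuple[str, str], int] | None = None,
        descriptions: dict[str, str] | None = None,
    ) -> None:
        self.sets = dict(sets or {})
        self.directions = dict(directions or {})
        self.descriptions = dict(descriptions or {})
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise GMTFormatError(f"duplicate members within set {name!r}")
        for (name, member), sign in self.directions.items():
            if sign not in (1, -1):
                raise GMTFormatError(
                    f"direction sign for {name!r}/{member!r} must be +1 or -1"
                )
            if member not in self.sets.get(name, ()):
                raise GMTFormatError(
                    f"direction references {member!r} absent from set {name!r}"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name]

    def set_directions(self, name: str) -> dict[str, int]:
        """Signed directions for one set as member -> sign."""
        return {m: s for (n, m), s in self.directions.items() if n == name}


def read_count_matrix(path: str | Path, design_path: str | Path) -> SpectralCountMatrix:
    """Read a TSV count matrix plus its run -> group design.

    The matrix header is ``accession``, ``length``, then one column per run.
    Non-integer or negative counts are rejected; every run must appear in the
    design and the design must contain at least two groups.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 3:
        raise MatrixFormatError(
            f"{path}: expected accession, length and at least one run column"
        )
    acc_col, len_col = df.columns[0], df.columns[1]
    accessions = df[acc_col].astype(str).tolist()
    dup = df[acc_col][df[acc_col].duplicated()]
    if len(dup):
        raise MatrixFormatError(f"{path}: duplicate accession {dup.iloc[0]!r}")
    lengths = pd.to_numeric(df[len_col], errors="raise").to_numpy()
    run_ids = [str(c) for c in df.columns[2:]]
    counts = df[df.columns[2:]].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise MatrixFormatError(f"{path}: non-numeric spectral counts")
    if np.any(counts != np.floor(counts)):
        raise MatrixFormatError(f"{path}: non-integer spectral counts")
    if counts.min() < 0:
        raise MatrixFormatError(f"{path}: negative spectral counts")

    design = pd.read_csv(design_path, sep="\t", dtype=str)
    if not {"run_id", "group"} <= set(design.columns):
        raise DesignError(f"{design_path}: needs columns run_id, group")
    groups = dict(zip(design["run_id"], design["group"]))
    missing = [r for r in run_ids if r not in groups]
    if missing:
        raise DesignError(f"{design_path}: runs missing from design: {missing}")
    if len(set(groups[r] for r in run_ids)) < 2:
        raise DesignError(f"{design_path}: fewer than two groups among the runs")
    return SpectralCountMatrix(
        accessions=accessions,
        lengths=lengths,
        counts=counts.astype(np.int64),
        run_ids=run_ids,
        groups={r: groups[r] for r in run_ids},
    )


def write_count_matrix(matrix: SpectralCountMatrix, path: str | Path,
                       design_path: str | Path | None = None) -> None:
    """Write a matrix (and optionally its design) back to TSV."""
    df = pd.DataFrame(matrix.counts, columns=matrix.run_ids)
    df.insert(0, "length", matrix.lengths)
    df.insert(0, "accession", matrix.accessions)
    df.to_csv(path, sep="\t", index=False)
    if design_path is not None:
        pd.DataFrame(
            {"run_id": matrix.run_ids,
             "group": [matrix.groups[r] for r in matrix.run_ids]}
        ).to_csv(design_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT gene-set file: one set per line, tab-separated
    ``name<TAB>description<TAB>member...``. Blank lines are skipped;
    duplicate members within a line are deduplicated with a warning.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTFormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning(
                    "%s:%d: duplicate members in set %r deduplicated",
                    path, lineno, name,
                )
            if name in sets:
                raise GMTFormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def read_directions(path: str | Path, collection: GeneSetCollection) -> GeneSetCollection:
    """Attach a signed-direction sidecar (set_name, member, sign) to *collection*.

    Returns a new collection; signs must be +1 or -1 and reference existing
    members.
    """
    df = pd.read_csv(path, sep="\t", dtype={"set_name": str, "member": str})
    if not {"set_name", "member", "sign"} <= set(df.columns):
        raise GMTFormatError(f"{path}: needs columns set_name, member, sign")
    directions: dict[tuple[str, str], int] = {}
    for _, row in df.iterrows():
        try:
            sign = int(row["sign"])
        except (TypeError, ValueError):
            raise GMTFormatError(f"{path}: sign {row['sign']!r} not +1/-1") from None
        if sign not in (1, -1):
            raise GMTFormatError(f"{path}: sign {sign} not +1/-1")
        directions[(row["set_name"], row["member"])] = sign
    return GeneSetCollection(
        sets=collection.sets,
        directions=directions,
        descriptions=collection.descriptions,
    )


# --- results tables ---------------------------------------------------------

DEP_COLUMNS = [
    "accession", "tier", "mean_spc_test", "mean_spc_ref",
    "mean_nsaf_test", "mean_nsaf_ref", "nsaf_ratio", "p_value", "category",
]
ENRICHMENT_COLUMNS = [
    "set_name", "k", "K", "n", "N", "p_value", "neg_log10_p",
    "z_score", "activation_state",
]


def _format_value(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        if math.isnan(v):
            return "NA"
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
        return FLOAT_FORMAT % v
    return str(v)


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    """Write a results table to TSV with a header and stable float rendering.

    Floats use the ``%.6g`` format and missing values render as ``NA`` so
    output files are byte-stable for a fixed input and round-trip through
    :func:`read_results`.
    """
    out = df.copy()
    for col in out.columns:
        out[col] = [_format_value(v) for v in out[col]]
    out.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    return df
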