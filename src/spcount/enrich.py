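"""Gene-set over-representation and directional activation scoring.

Two independent questions are asked of each gene set:

1. *Is the set over-represented among the DEPs?* — answered by the
   hypergeometric upper tail: with a universe of N detected proteins, K of
   which belong to the set, and a DEP list of size n overlapping the set in
   k proteins, p = P[X >= k] for X ~ Hypergeometric(N, K, n). Ranking sets
   by -log10(p) reproduces the usual "top canonical pathways" bar chart.

2. *Is the set activated or deactivated?* — answered by the additive
   activation z-score over directionally annotated members. Each scoreable
   member contributes +1 when its observed expression direction matches the
   direction expected under activation (consistent) and -1 otherwise:

   .. math:: z = (n_{consistent} - n_{inconsistent}) / \\sqrt{n_{consistent} + n_{inconsistent}}

   z > 2 predicts activation, z < -2 deactivation (strict inequalities);
   anything else, including sets with no scoreable member, yields no
   prediction.

Observed directions come from DEP categories: overexpressed -> +1,
underexpressed -> -1; uniquely expressed proteins contribute +1 (test
group) or -1 (reference group) by default since they are part of the DEP
evidence, and this can be switched off. Unchanged proteins never score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dep import DEPRecord
from .io import ENRICHMENT_COLUMNS, GeneSetCollection
from .nsaf import NSAFTable

logger = logging.getLogger(__name__)

DEP_CATEGORIES = ("overexpressed", "underexpressed", "unique_test", "unique_reference")


class ContractError(ValueError):
    """Inconsistent counts or universes passed to an enrichment operation."""


@dataclass
class EnrichmentRecord:
    set_name: str
    k: int  # overlap between set and DEP list
    K: int  # set size within the universe
    n: int  # DEP-list size
    N: int  # universe size
    p_value: float
    neg_log10_p: float
    z_score: float | None
    activation_state: str  # activated | deactivated | no_prediction


def overrepresentation_p(k: int, K: int, n: int, N: int) -> float:
    """Hypergeometric upper-tail P[X >= k] for X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ContractError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def observed_signs(
    records: list[DEPRecord], include_unique: bool = True
) -> dict[str, int]:
    """Observed expression direction per DEP accession (+1 up, -1 down)."""
    signs: dict[str, int] = {}
    for r in records:
        if r.category == "overexpressed":
            signs[r.accession] = 1
        elif r.category == "underexpressed":
            signs[r.accession] = -1
        elif include_unique and r.category == "unique_test":
            signs[r.accession] = 1
        elif include_unique and r.category == "unique_reference":
            signs[r.accession] = -1
    return signs


def activation_zscore(
    directions: dict[str, int], observed: dict[str, int]
) -> float | None:
    """Additive activation z-score over directionally annotated members.

    *directions* maps member -> expected sign under activation; *observed*
    maps accession -> observed sign. Members lacking either annotation are
    ignored. Returns None when no member is scoreable. Antisymmetric:
    flipping every observed sign negates z.
    """
    consistent = inconsistent = 0
    for member, expected in directions.items():
        obs = observed.get(member)
        if obs is None:
            continue
        if obs == expected:
            consistent += 1
        else:
            inconsistent += 1
    total = consistent + inconsistent
    if total == 0:
        return None
    return (consistent - inconsistent) / math.sqrt(total)


def call_activation_state(z: float | None) -> str:
    """Map a z-score to activated / deactivated / no_prediction.

    Strict inequalities: z must exceed 2 (or fall below -2); exactly +/-2
    and undefined z give no prediction.
    """
    if z is None:
        return "no_prediction"
    if z > 2:
        return "activated"
    if z < -2:
        return "deactivated"
    return "no_prediction"


def enrich_all(
    records: list[DEPRecord],
    sets: GeneSetCollection,
    universe: list[str] | None = None,
    include_unique_in_z: bool = True,
) -> list[EnrichmentRecord]:
    """Score every gene set against the DEP list.

    The universe defaults to all proteins detected in the analysis (every
    record not below detection). Set members outside the universe do not
    count toward K. Records are sorted by p ascending, ties broken by set
    name.
    """
    detected = [r.accession for r in records if r.category != "below_detection"]
    if universe is None:
        universe_set = set(detected)
        N = len(universe_set)
    else:
        universe_set = set(universe)
        N = len(universe_set)
    dep_accessions = {r.accession for r in records if r.category in DEP_CATEGORIES}
    outside = dep_accessions - universe_set
    if outside:
        raise ContractError(
            f"DEP accessions outside the universe: {sorted(outside)[:5]}"
        )
    signs = observed_signs(records, include_unique=include_unique_in_z)

    out: list[EnrichmentRecord] = []
    for name in sets:
        members = sets.members(name)
        in_universe = [m for m in members if m in universe_set]
        K = len(in_universe)
        k = sum(1 for m in in_universe if m in dep_accessions)
        n = len(dep_accessions)
        p = overrepresentation_p(k, K, n, N)
        z = activation_zscore(sets.set_directions(name), signs)
        out.append(EnrichmentRecord(
            set_name=name, k=k, K=K, n=n, N=N,
            p_value=p, neg_log10_p=-math.log10(p) if p > 0 else math.inf,
            z_score=z, activation_state=call_activation_state(z),
        ))
    out.sort(key=lambda r: (r.p_value, r.set_name))
    return out


def enrichment_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "set_name": r.set_name, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
            "p_value": r.p_value, "neg_log10_p": r.neg_log10_p,
            "z_score": r.z_score, "activation_state": r.activation_state,
        }
        for r in records
    ], columns=ENRICHMENT_COLUMNS)


def export_heatmap_matrix(
    records: list[DEPRecord],
    members: list[str],
    nsaf: NSAFTable,
    test_group: str,
    ref_group: str,
) -> pd.DataFrame:
    """Set-member proteins x groups mean-NSAF matrix for heat-map plotting.

    Rows follow the set's member order; columns are the two group mean
    NSAFs plus log2(test/ref). Members absent from the analysis are
    dropped (warned when the intersection is empty).
    """
    index = {a: i for i, a in enumerate(nsaf.accessions)}
    rows = []
    for m in members:
        i = index.get(m)
        if i is None:
            continue
        a = float(nsaf.group_mean_nsaf[test_group][i])
        b = float(nsaf.group_mean_nsaf[ref_group][i])
        if a > 0 and b > 0:
            log_ratio = math.log2(a / b)
        else:
            log_ratio = math.nan
        rows.append({
            "accession": m,
            f"mean_nsaf_{test_group}": a,
            f"mean_nsaf_{ref_group}": b,
            "log2_ratio": log_ratio,
        })
    if not rows:
        logger.warning("gene set has no members in the analysis; empty matrix")
    return pd.DataFrame(rows, columns=[
        "accession", f"mean_nsaf_{test_group}", f"mean_nsaf_{ref_group}",
        "log2_ratio",
    ])
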