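"""Pedigree statistics for ascertained family samples.

Implements the quantities used to characterise samples of multiplex
pedigrees: recursive kinship coefficients, the familial-clustering
statistic ``A_IBD`` (mean pairwise IBD-sharing probability ``2 * phi``
among affected relatives), relationship degree, generation assignment
relative to the affecteds' most recent common ancestor (used to display
apparent anticipation), the matching negative-control table of death ages
in unaffected relatives, per-family and per-affected summary tables, and
the estimator of the proportion of ascertained families segregating a
causal variant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "FamilySummary",
    "kinship",
    "kinship_matrix",
    "a_ibd",
    "relationship_degree",
    "most_recent_common_ancestor",
    "assign_generation",
    "anticipation_tables",
    "summarize_family",
    "family_tables",
    "proportion_segregating",
    "FAMILY_INFO_COLUMNS",
    "AFFECTED_INFO_COLUMNS",
]

FAMILY_INFO_COLUMNS = [
    "FamID",
    "totalRelatives",
    "numAffected",
    "aveOnsetAge",
    "aveIBD",
    "ascertainYear",
    "segRV",
]
AFFECTED_INFO_COLUMNS = [
    "FamID",
    "ID",
    "birthYr",
    "onsetYr",
    "deathYr",
    "RR",
    "proband",
    "RVstatus",
]


@dataclass(frozen=True)
class FamilySummary:
    """One family's summary row (the ``family_info`` record)."""

    family_id: int
    total_relatives: int
    total_affected: int
    ave_onset_age: float
    ave_ibd: float
    ascertain_year: Optional[int]
    segregates_variant: bool


def kinship_matrix(ped: Pedigree) -> pd.DataFrame:
    """All pairwise kinship coefficients, via the recursive tabular method.

    Members are processed parents-before-children; ``phi(x, x) =
    0.5 * (1 + phi(father, mother))`` and ``phi(child, y) =
    (phi(father, y) + phi(mother, y)) / 2`` for earlier ``y``.  Founders
    are assumed non-inbred and mutually unrelated.
    """
    order = ped.topological_order()
    n = len(order)
    idx = {iid: i for i, iid in enumerate(order)}
    phi = np.zeros((n, n))
    for i, iid in enumerate(order):
        ind = ped[iid]
        if ind.father_id is None:
            phi[i, i] = 0.5
        else:
            fi, mi = idx[ind.father_id], idx[ind.mother_id]
            phi[i, i] = 0.5 * (1.0 + phi[fi, mi])
            for j in range(i):
                phi[i, j] = phi[j, i] = 0.5 * (phi[fi, j] + phi[mi, j])
    return pd.DataFrame(phi, index=order, columns=order)


def kinship(ped: Pedigree, a: int, b: int) -> float:
    """Kinship coefficient ``phi(a, b)`` between two pedigree members."""
    if a not in ped or b not in ped:
        missing = a if a not in ped else b
        raise KeyError(f"individual {missing} not in family {ped.family_id}")
    return float(kinship_matrix(ped).loc[a, b])


def relationship_degree(phi: float) -> int:
    """Relationship degree implied by a kinship coefficient (1 for phi=1/4, ...)."""
    if phi <= 0:
        raise ValueError("relationship degree undefined for unrelated individuals")
    return max(1, round(-math.log2(2.0 * phi)))


def a_ibd(ped: Pedigree, members: Iterable[int]) -> float:
    """Mean pairwise IBD probability ``2 * phi`` over the given members.

    For an affected parent-child pair or sibling pair this equals 0.5; for
    an avuncular or grandparent-grandchild pair, 0.25.
    """
    ids = sorted(set(members))
    if len(ids) < 2:
        raise ValueError("a_ibd requires at least two members")
    phi = kinship_matrix(ped)
    vals = [2.0 * phi.loc[a, b] for a, b in itertools.combinations(ids, 2)]
    return float(np.mean(vals))


def _ancestors_or_self(ped: Pedigree, iid: int) -> Set[int]:
    return ped.ancestors(iid) | {iid}


def _depth_to(ped: Pedigree, iid: int, ancestor: int) -> int:
    """Minimum number of parent links from ``iid`` up to ``ancestor``."""
    if iid == ancestor:
        return 0
    frontier = {iid}
    d = 0
    while frontier:
        d += 1
        nxt: Set[int] = set()
        for cur in frontier:
            ind = ped[cur]
            for pid in (ind.father_id, ind.mother_id):
                if pid == ancestor:
                    return d
                if pid is not None:
                    nxt.add(pid)
        frontier = nxt
    raise ValueError(f"{ancestor} is not an ancestor of {iid}")


def most_recent_common_ancestor(ped: Pedigree, members: Iterable[int]) -> int:
    """Most recent member from whom all of ``members`` could inherit a variant IBD.

    A member may be its own most recent common ancestor.  Among common
    ancestors the one minimising the maximum parent-link depth to the
    members is chosen (ties: smallest total depth, then smallest id; the
    two members of an ancestral couple are equivalent under this rule and
    count as a single generation).
    """
    ids = sorted(set(members))
    if not ids:
        raise ValueError("need at least one member")
    common = set.intersection(*(_ancestors_or_self(ped, i) for i in ids))
    if not common:
        raise ValueError(
            f"family {ped.family_id}: members {ids} share no common ancestor"
        )

    def key(anc: int):
        depths = [_depth_to(ped, i, anc) for i in ids]
        return (max(depths), sum(depths), anc)

    return min(common, key=key)


def assign_generation(ped: Pedigree, affecteds: Iterable[int]) -> Dict[int, int]:
    """Generation numbers among affected members for anticipation displays.

    Generation 1 is the most recent common ancestor with whom all affecteds
    could share a variant identical by descent (an affected may be its own
    MRCA); every affected is numbered ``1 + depth`` below that ancestor.
    An affected parent-child pair is numbered 1 and 2; an affected sibling
    pair is numbered 2 and 2.
    """
    ids = sorted(set(affecteds))
    mrca = most_recent_common_ancestor(ped, ids)
    return {i: 1 + _depth_to(ped, i, mrca) for i in ids}


def anticipation_tables(
    study: Sequence,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Onset-age table by assigned generation, plus the death-age negative control.

    The onset table has one row per affected relative with known onset and
    birth years; the control table holds death ages of *unaffected*
    relatives (known status) that descend from the affecteds' most recent
    common ancestor, numbered by depth below the same ancestor.  Members
    with missing status (trimmed connectors, married-ins) appear in
    neither table.
    """
    onset_rows: List[dict] = []
    death_rows: List[dict] = []
    for item in study:
        ped: Pedigree = getattr(item, "ascertained_ped", item)
        affecteds = [
            m.individual_id
            for m in ped
            if m.affected is True and m.onset_year is not None and m.birth_year is not None
        ]
        if not affecteds:
            continue
        mrca = most_recent_common_ancestor(ped, affecteds)
        for iid in affecteds:
            m = ped[iid]
            onset_rows.append(
                {
                    "FamID": ped.family_id,
                    "ID": iid,
                    "generation": 1 + _depth_to(ped, iid, mrca),
                    "onset_age": m.onset_year - m.birth_year,
                }
            )
        for m in ped:
            if m.affected is not False:
                continue
            if m.death_year is None or m.birth_year is None:
                continue
            if mrca not in _ancestors_or_self(ped, m.individual_id):
                continue
            death_rows.append(
                {
                    "FamID": ped.family_id,
                    "ID": m.individual_id,
                    "generation": 1 + _depth_to(ped, m.individual_id, mrca),
                    "death_age": m.death_year - m.birth_year,
                }
            )
    cols_on = ["FamID", "ID", "generation", "onset_age"]
    cols_de = ["FamID", "ID", "generation", "death_age"]
    onset = pd.DataFrame(onset_rows, columns=cols_on)
    death = pd.DataFrame(death_rows, columns=cols_de)
    return onset, death


def summarize_family(pair_or_ped) -> Tuple[FamilySummary, List[dict]]:
    """Per-family summary plus one row per disease-affected relative.

    Accepts an ascertained pair (uses its ascertained pedigree) or a bare
    pedigree.  The ascertainment year is the proband's onset year (the
    proband contacts the study at onset); ``A_IBD`` is NaN for families
    with fewer than two affecteds.
    """
    ped: Pedigree = getattr(pair_or_ped, "ascertained_ped", pair_or_ped)
    affected = [ped[i] for i in ped.affected_ids()]
    onset_ages = [
        m.onset_year - m.birth_year
        for m in affected
        if m.onset_year is not None and m.birth_year is not None
    ]
    ave_onset = float(np.mean(onset_ages)) if onset_ages else math.nan
    if len(affected) >= 2:
        ave_ibd = a_ibd(ped, [m.individual_id for m in affected])
    else:
        ave_ibd = math.nan
    probands = [m for m in ped if m.proband]
    ascertain_year = probands[0].onset_year if probands else None
    summary = FamilySummary(
        family_id=ped.family_id,
        total_relatives=len(ped),
        total_affected=len(affected),
        ave_onset_age=ave_onset,
        ave_ibd=ave_ibd,
        ascertain_year=ascertain_year,
        segregates_variant=ped.seg_variant,
    )
    rows = [
        {
            "FamID": ped.family_id,
            "ID": m.individual_id,
            "birthYr": m.birth_year,
            "onsetYr": m.onset_year,
            "deathYr": m.death_year,
            "RR": m.relative_risk,
            "proband": m.proband,
            "RVstatus": m.carrier,
        }
        for m in sorted(affected, key=lambda m: m.individual_id)
    ]
    return summary, rows


def family_tables(study: Sequence) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """``family_info`` and ``affected_info`` tables for a study sample."""
    fam_rows: List[dict] = []
    aff_rows: List[dict] = []
    for item in study:
        summary, rows = summarize_family(item)
        fam_rows.append(
            {
                "FamID": summary.family_id,
                "totalRelatives": summary.total_relatives,
                "numAffected": summary.total_affected,
                "aveOnsetAge": summary.ave_onset_age,
                "aveIBD": summary.ave_ibd,
                "ascertainYear": summary.ascertain_year,
                "segRV": summary.segregates_variant,
            }
        )
        aff_rows.extend(rows)
    family_info = pd.DataFrame(fam_rows, columns=FAMILY_INFO_COLUMNS)
    affected_info = pd.DataFrame(aff_rows, columns=AFFECTED_INFO_COLUMNS)
    return family_info, affected_info


def proportion_segregating(study: Sequence, min_affected: int = 2) -> float:
    """Fraction of families with >= ``min_affected`` affecteds that segregate the variant.

    Returns NaN when no family meets the threshold (reported as undefined
    rather than zero).
    """
    flags = []
    for item in study:
        ped: Pedigree = getattr(item, "ascertained_ped", item)
        if len(ped.affected_ids()) >= min_affected:
            flags.append(ped.seg_variant)
    if not flags:
        return math.nan
    return float(np.mean(flags))
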