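"""Proband selection, recall-based trimming, and study-level ascertainment.

A family enters the study through a proband: a disease-affected member
whose onset falls inside the ascertainment span and who was at least the
``num_affected``-th member of the family to develop disease.  The proband's
imperfect recall of relatives is modelled by independently retaining each
blood relative with a relationship-dependent probability; by default this is
four times the kinship coefficient with the proband (1 for first-degree,
0.5 for second-degree, 0.25 for third-degree relatives, ...).  Relatives
that were not recalled but are required to connect the recalled members are
kept as unavailable "connectors" with all their information set missing.
If trimming drops the family below ``num_affected`` affected members, the
whole pedigree is discarded and a new one simulated.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .hazards import HazardModel
from .pedigree import Individual, Pedigree, simulate_pedigree
from . import stats as _stats

__all__ = [
    "StudyConfig",
    "AscertainedPair",
    "AscertainmentError",
    "find_proband",
    "default_recall",
    "resolve_recall",
    "trim_by_recall",
    "ascertain_pedigree",
    "simulate_study",
]


class AscertainmentError(RuntimeError):
    """Raised when no valid pedigree is found within the attempt ceiling."""


@dataclass(frozen=True)
class StudyConfig:
    """Family-study design parameters.

    ``recall_probs`` is either the string ``"default"`` (recall probability
    = four times the kinship coefficient with the proband) or a sequence
    ``(p_1, ..., p_q)`` applied by relationship degree, with relatives of
    degree >= q recalled with probability ``p_q``.
    """

    num_affected: int = 2
    ascertain_span: Tuple[int, int] = (2000, 2015)
    stop_year: int = 2017
    recall_probs: Union[str, Tuple[float, ...]] = "default"
    kappa: float = 1.0
    carrier_prob: float = 0.002
    variant_mode: str = "eldest_founder"
    founder_birth_range: Tuple[int, int] = (1900, 1980)
    onset_scale: float = 1.0
    seed: Optional[int] = None
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.num_affected < 1:
            raise ValueError("num_affected must be >= 1")
        start, end = self.ascertain_span
        if not (start <= end <= self.stop_year):
            raise ValueError(
                f"require ascertain_span start <= end <= stop_year; "
                f"got {self.ascertain_span} with stop_year {self.stop_year}"
            )
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if not 0 <= self.carrier_prob <= 1:
            raise ValueError("carrier_prob must lie in [0, 1]")
        if self.variant_mode not in ("eldest_founder", "bernoulli"):
            raise ValueError(f"unknown variant_mode {self.variant_mode!r}")
        if not isinstance(self.recall_probs, str):
            probs = tuple(float(p) for p in self.recall_probs)
            if not probs or any(not 0 <= p <= 1 for p in probs):
                raise ValueError("recall probabilities must lie in [0, 1]")
            object.__setattr__(self, "recall_probs", probs)
        elif self.recall_probs != "default":
            raise ValueError(f"recall_probs must be 'default' or a sequence; got {self.recall_probs!r}")
        lo, hi = self.founder_birth_range
        if lo > hi:
            raise ValueError("founder_birth_range must be (low, high)")


@dataclass
class AscertainedPair:
    """A simulated family before and after ascertainment.

    ``full_ped`` is the original pedigree; ``ascertained_ped`` has the
    proband marked and unrecalled relatives trimmed.
    """

    full_ped: Pedigree
    ascertained_ped: Pedigree
    proband_id: int
    attempts: int = 1

    def validate(self, config: StudyConfig) -> None:
        ped = self.ascertained_ped
        probands = [m for m in ped if m.proband]
        if len(probands) != 1 or probands[0].individual_id != self.proband_id:
            raise AscertainmentError(
                f"family {ped.family_id}: expected exactly one proband ({self.proband_id})"
            )
        pro = probands[0]
        start, end = config.ascertain_span
        if pro.affected is not True or not pro.available:
            raise AscertainmentError(f"family {ped.family_id}: proband not affected/available")
        if not (start <= pro.onset_year <= end):
            raise AscertainmentError(
                f"family {ped.family_id}: proband onset {pro.onset_year} outside span"
            )
        if len(ped.affected_ids()) < config.num_affected:
            raise AscertainmentError(
                f"family {ped.family_id}: fewer than {config.num_affected} affecteds after trimming"
            )
        if not ped.is_connected():
            raise AscertainmentError(f"family {ped.family_id}: trimmed pedigree disconnected")


def _onset_order(ped: Pedigree) -> List[int]:
    """Affected members ordered by onset year, tie-broken by onset age then id."""
    affecteds = [m for m in ped if m.affected is True and m.onset_year is not None]

    def key(m: Individual):
        onset_age = (
            m.onset_year - m.birth_year if m.birth_year is not None else math.inf
        )
        return (m.onset_year, onset_age, m.individual_id)

    return [m.individual_id for m in sorted(affecteds, key=key)]


def find_proband(ped: Pedigree, config: StudyConfig, rng: np.random.Generator) -> Optional[int]:
    """Choose a proband uniformly among the eligible members, or ``None``.

    Eligible: affected, onset year inside the ascertainment span, and at
    least the ``num_affected``-th member of the family to develop disease
    (by onset order).
    """
    order = _onset_order(ped)
    start, end = config.ascertain_span
    eligible = [
        iid
        for rank, iid in enumerate(order, start=1)
        if rank >= config.num_affected and start <= ped[iid].onset_year <= end
    ]
    if not eligible:
        return None
    return int(rng.choice(eligible))


def default_recall(ped: Pedigree, proband: int) -> Dict[int, float]:
    """Recall probability ``min(1, 4 * kinship)`` for every non-proband member."""
    if proband not in ped:
        raise KeyError(f"proband {proband} not in family {ped.family_id}")
    phi = _stats.kinship_matrix(ped)
    return {
        m.individual_id: min(1.0, 4.0 * phi.loc[proband, m.individual_id])
        for m in ped
        if m.individual_id != proband
    }


def resolve_recall(config: StudyConfig, ped: Pedigree, proband: int) -> Dict[int, float]:
    """Per-member recall probabilities for the configured rule.

    With a user vector ``(p_1, ..., p_q)``, each blood relative's
    relationship degree ``d`` is derived from the kinship coefficient as
    ``d = round(-log2(2 * phi))`` and the relative receives ``p_min(d, q)``;
    unrelated members (married-ins) receive 1 (they are governed by the
    co-parent retention rule instead).
    """
    if config.recall_probs == "default":
        return default_recall(ped, proband)
    probs: Tuple[float, ...] = config.recall_probs  # type: ignore[assignment]
    q = len(probs)
    phi = _stats.kinship_matrix(ped)
    out: Dict[int, float] = {}
    for m in ped:
        if m.individual_id == proband:
            continue
        p = phi.loc[proband, m.individual_id]
        if p <= 0:
            out[m.individual_id] = 1.0
            continue
        degree = max(1, round(-math.log2(2.0 * p)))
        out[m.individual_id] = probs[min(degree, q) - 1]
    return out


def _strip(ind: Individual) -> Individual:
    """Connector copy: unavailable, disease status / risk / event years missing."""
    return Individual(
        family_id=ind.family_id,
        individual_id=ind.individual_id,
        sex=ind.sex,
        father_id=ind.father_id,
        mother_id=ind.mother_id,
        carrier=ind.carrier,
        affected=None,
        birth_year=None,
        onset_year=None,
        death_year=None,
        available=False,
        proband=False,
        relative_risk=None,
    )


def trim_by_recall(
    ped: Pedigree,
    proband: int,
    recall: Dict[int, float],
    rng: np.random.Generator,
) -> Pedigree:
    """Trim relatives the proband fails to recall; keep required connectors.

    Every blood relative except the proband is independently retained with
    its recall probability.  The retained members are then joined into a
    valid pedigree by re-adding, as unavailable connectors with missing
    information, any dropped individual lying on a lineage path between
    retained members.  A married-in co-parent is kept iff at least one of
    its offspring is kept.
    """
    lineage = ped.lineage_ids()
    retained: Set[int] = {proband}
    for iid in sorted(lineage):
        if iid == proband:
            continue
        if rng.random() < recall.get(iid, 1.0):
            retained.add(iid)

    # Lineage members form a rooted tree via their single lineage parent;
    # the minimal connecting set is the union of pairwise tree paths.
    def path_to_root(iid: int) -> List[int]:
        path = [iid]
        cur = ped[iid]
        while cur.father_id is not None:
            nxt = cur.father_id if cur.father_id in lineage else cur.mother_id
            path.append(nxt)
            cur = ped[nxt]
        return path

    root_paths = {iid: path_to_root(iid) for iid in retained}
    needed: Set[int] = set(retained)
    ret = sorted(retained)
    for i, a in enumerate(ret):
        pa = root_paths[a]
        sa = set(pa)
        for b in ret[i + 1 :]:
            pb = root_paths[b]
            # lowest common ancestor = first node of b's root path found in a's
            lca = next(x for x in pb if x in sa)
            needed.update(pa[: pa.index(lca) + 1])
            needed.update(pb[: pb.index(lca) + 1])

    out = Pedigree(
        ped.family_id,
        founder_id=ped.founder_id if ped.founder_id in needed else None,
    )
    # A kept child retains its parent links only when its lineage parent is
    # kept too (the subtree root's parents are dropped entirely); a
    # married-in co-parent is kept iff it co-parents such a child.
    def lineage_parent(iid: int) -> Optional[int]:
        ind = ped[iid]
        if ind.father_id is None:
            return None
        return ind.father_id if ind.father_id in lineage else ind.mother_id

    keeps_parents = {
        iid for iid in needed if lineage_parent(iid) is not None and lineage_parent(iid) in needed
    }
    kept_marryins = {
        m.individual_id
        for m in ped
        if m.individual_id not in lineage
        and any(c in keeps_parents for c in ped.children(m.individual_id))
    }
    for iid in sorted(needed | kept_marryins):
        src = ped[iid]
        if iid in needed and iid not in retained:
            ind = _strip(src)
        else:
            ind = dataclasses.replace(src)
        if ind.father_id is not None and iid not in keeps_parents:
            ind.father_id = None
            ind.mother_id = None
        out.add(ind)
    return out


def ascertain_pedigree(
    config: StudyConfig,
    hazards: HazardModel,
    rng: np.random.Generator,
    family_id: int = 1,
) -> AscertainedPair:
    """Simulate pedigrees until one satisfies every ascertainment condition.

    Each attempt simulates a full pedigree, looks for an eligible proband,
    and trims by recall; the attempt is accepted only if the trimmed
    pedigree still contains at least ``num_affected`` members with
    non-missing affected status.  Fails loudly after ``max_attempts``.
    """
    for attempt in range(1, config.max_attempts + 1):
        ped = simulate_pedigree(config, hazards, rng, family_id=family_id)
        proband = find_proband(ped, config, rng)
        if proband is None:
            continue
        recall = resolve_recall(config, ped, proband)
        trimmed = trim_by_recall(ped, proband, recall, rng)
        if len(trimmed.affected_ids()) < config.num_affected:
            continue
        trimmed[proband].proband = True
        pair = AscertainedPair(
            full_ped=ped, ascertained_ped=trimmed, proband_id=proband, attempts=attempt
        )
        pair.validate(config)
        return pair
    raise AscertainmentError(
        f"family {family_id}: no pedigree met the ascertainment criteria in "
        f"{config.max_attempts} attempts (check hazards/span/num_affected)"
    )


def simulate_study(
    config: StudyConfig,
    hazards: HazardModel,
    n_families: int,
    seed: Optional[int] = None,
) -> List[AscertainedPair]:
    """Simulate ``n_families`` independently ascertained pedigrees.

    Each family uses its own generator seeded from the master seed and the
    family index, so serial and parallel (or partial) runs agree family by
    family.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    master = seed if seed is not None else config.seed
    if master is None:
        raise ValueError("a seed is required (StudyConfig.seed or the seed argument)")
    pairs: List[AscertainedPair] = []
    for fam in range(1, n_families + 1):
        ss = np.random.SeedSequence(entropy=int(master), spawn_key=(fam,))
        rng = np.random.default_rng(ss)
        pairs.append(ascertain_pedigree(config, hazards, rng, family_id=fam))
    return pairs
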