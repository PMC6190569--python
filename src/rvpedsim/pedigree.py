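"""Pedigree container and recursive pedigree growth.

A pedigree is grown from a single starting founder.  The founder's rare
variant status is set either deterministically (``eldest_founder``: the
variant is rare enough that exactly one founder introduced it) or by a
Bernoulli draw with the population carrier probability (``bernoulli``: some
simulated families are then fully sporadic).  The variant is transmitted
parent-to-offspring by Mendel's laws (probability 1/2 from a carrier
parent), so at most one founder ever carries it and all carriers form a
connected sub-lineage.

Life events for the founder and every descendant are simulated with
:func:`rvpedsim.life_history.simulate_life`; each reproduction event adds an
offspring whose own life is then simulated.  A single married-in co-parent
is created per lineage member at their first reproduction; married-ins are
non-carriers whose own life history is not modelled (no event years, missing
disease status).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Set, Tuple

import numpy as np

from .hazards import DiseaseModel, HazardModel
from .life_history import (
    EventKind,
    IndividualState,
    ReproductionModel,
    assign_birth_traits,
    simulate_life,
)

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "introduce_variant",
    "transmit_variant",
    "simulate_pedigree",
]


class PedigreeError(ValueError):
    """Raised on structurally invalid pedigrees."""


@dataclass
class Individual:
    """One pedigree member.

    ``affected`` is ``True``/``False`` for members with simulated (or
    recalled) life histories and ``None`` when the status is missing —
    married-in co-parents and trimmed connectors.  ``available`` is
    ``False`` only for connectors re-added during recall trimming.
    """

    family_id: int
    individual_id: int
    sex: str  # 'M' or 'F'
    father_id: Optional[int] = None
    mother_id: Optional[int] = None
    carrier: bool = False
    affected: Optional[bool] = False
    birth_year: Optional[int] = None
    onset_year: Optional[int] = None
    death_year: Optional[int] = None
    available: bool = True
    proband: bool = False
    relative_risk: Optional[float] = 1.0

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise PedigreeError(f"sex must be 'M' or 'F'; got {self.sex!r}")
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.individual_id}: parents must be both present or both absent"
            )
        if self.birth_year is not None and self.onset_year is not None:
            if self.onset_year < self.birth_year:
                raise PedigreeError(
                    f"individual {self.individual_id}: onset year precedes birth year"
                )
        if self.onset_year is not None and self.death_year is not None:
            if self.death_year < self.onset_year:
                raise PedigreeError(
                    f"individual {self.individual_id}: death year precedes onset year"
                )

    @property
    def is_founder(self) -> bool:
        """No parents within the pedigree (starting founder or married-in)."""
        return self.father_id is None


class Pedigree:
    """A family of :class:`Individual` members with parent-graph queries."""

    def __init__(self, family_id: int, founder_id: Optional[int] = None):
        self.family_id = family_id
        self.founder_id = founder_id
        self.members: Dict[int, Individual] = {}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.members.values())

    def __contains__(self, individual_id: int) -> bool:
        return individual_id in self.members

    def __getitem__(self, individual_id: int) -> Individual:
        try:
            return self.members[individual_id]
        except KeyError:
            raise KeyError(
                f"no individual {individual_id} in family {self.family_id}"
            ) from None

    def add(self, ind: Individual) -> None:
        if ind.individual_id in self.members:
            raise PedigreeError(
                f"duplicate individual id {ind.individual_id} in family {self.family_id}"
            )
        self.members[ind.individual_id] = ind

    # -- graph queries ------------------------------------------------------
    def parents(self, individual_id: int) -> Optional[Tuple[int, int]]:
        ind = self[individual_id]
        if ind.father_id is None:
            return None
        return ind.father_id, ind.mother_id

    def children(self, individual_id: int) -> List[int]:
        return [
            m.individual_id
            for m in self
            if individual_id in (m.father_id, m.mother_id)
        ]

    def founders(self) -> List[int]:
        return [m.individual_id for m in self if m.is_founder]

    def ancestors(self, individual_id: int) -> Set[int]:
        """All ancestors of ``individual_id`` (excluding itself)."""
        seen: Set[int] = set()
        stack = [individual_id]
        while stack:
            cur = self[stack.pop()]
            for pid in (cur.father_id, cur.mother_id):
                if pid is not None and pid not in seen:
                    seen.add(pid)
                    stack.append(pid)
        return seen

    def lineage_ids(self) -> Set[int]:
        """Members with simulated life histories: the starting founder and
        everyone with parents in the pedigree (i.e. everyone except
        married-in co-parents)."""
        ids = {m.individual_id for m in self if not m.is_founder}
        if self.founder_id is not None and self.founder_id in self.members:
            ids.add(self.founder_id)
        else:
            # reconstructed pedigree: any founder with a recorded birth year
            # belongs to the lineage
            ids |= {
                m.individual_id for m in self if m.is_founder and m.birth_year is not None
            }
        return ids

    def topological_order(self) -> List[int]:
        """Member ids ordered so every parent precedes all of its children."""
        order: List[int] = []
        placed: Set[int] = set()
        pending = deque(sorted(self.members))
        guard = 0
        while pending:
            iid = pending.popleft()
            ind = self.members[iid]
            if ind.father_id is None or (
                ind.father_id in placed and ind.mother_id in placed
            ):
                order.append(iid)
                placed.add(iid)
                guard = 0
            else:
                pending.append(iid)
                guard += 1
                if guard > len(pending):
                    raise PedigreeError(
                        f"family {self.family_id}: cyclic or dangling parentage "
                        f"involving individual {iid}"
                    )
        return order

    def depth(self) -> Dict[int, int]:
        """Generation depth per member: 0 for the top generation; a child is
        one below its deeper parent; a married-in sits at its child's depth
        minus one."""
        d: Dict[int, int] = {}
        for iid in self.topological_order():
            ind = self.members[iid]
            if ind.father_id is None:
                d[iid] = 0
            else:
                d[iid] = max(d[ind.father_id], d[ind.mother_id]) + 1
        # lift married-ins next to their mates
        for m in self:
            if m.is_founder:
                kids = self.children(m.individual_id)
                if kids:
                    d[m.individual_id] = min(d[k] for k in kids) - 1
        return d

    def is_connected(self) -> bool:
        """Connectivity of the undirected parent-child graph."""
        if not self.members:
            return True
        ids = set(self.members)
        start = next(iter(ids))
        seen = {start}
        stack = [start]
        while stack:
            cur = stack.pop()
            ind = self.members[cur]
            nbrs = [p for p in (ind.father_id, ind.mother_id) if p is not None]
            nbrs += self.children(cur)
            for nb in nbrs:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen == ids

    @property
    def seg_variant(self) -> bool:
        """True iff at least one member carries the rare variant."""
        return any(m.carrier for m in self)

    def affected_ids(self) -> List[int]:
        """Members with non-missing affected status equal to True."""
        return [m.individual_id for m in self if m.affected is True]

    def validate(self) -> None:
        """Check structural invariants; raises :class:`PedigreeError`."""
        for m in self:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in self.members:
                    raise PedigreeError(
                        f"family {self.family_id}, individual {m.individual_id}: "
                        f"parent {pid} not in pedigree"
                    )
        self.topological_order()  # raises on cycles
        carriers = [m for m in self if m.carrier]
        carrier_founders = [m for m in carriers if m.is_founder]
        if len(carrier_founders) > 1:
            raise PedigreeError(
                f"family {self.family_id}: {len(carrier_founders)} carrier founders; "
                f"the variant may be introduced by at most one"
            )

    def copy(self) -> "Pedigree":
        out = Pedigree(self.family_id, self.founder_id)
        for m in self:
            out.add(replace(m))
        return out


def introduce_variant(mode: str, carrier_prob: float, rng: np.random.Generator) -> bool:
    """Rare-variant status of the starting founder.

    ``eldest_founder``: the starting founder always carries (the variant was
    introduced by exactly one founder).  ``bernoulli``: carries with
    probability ``carrier_prob``, so some families are fully sporadic.
    """
    if mode == "eldest_founder":
        return True
    if mode == "bernoulli":
        return bool(rng.random() < carrier_prob)
    raise ValueError(f"unknown variant introduction mode {mode!r}")


def transmit_variant(parent_carrier: bool, rng: np.random.Generator) -> bool:
    """Mendelian transmission: probability 1/2 from a carrier parent, else 0."""
    if not parent_carrier:
        return False
    return bool(rng.random() < 0.5)


def simulate_pedigree(
    config,
    hazards: HazardModel,
    rng: np.random.Generator,
    family_id: int = 1,
    repro: Optional[ReproductionModel] = None,
) -> Pedigree:
    """Grow one full pedigree from a starting founder.

    The founder's birth year is drawn uniformly (integer years) over
    ``config.founder_birth_range``; the founder's carrier status follows
    ``config.variant_mode``.  Life events are simulated founder-first, then
    recursively for every offspring produced by a reproduction event, until
    all descendants are processed or censored at ``config.stop_year``.
    """
    if repro is None:
        repro = ReproductionModel(onset_scale=config.onset_scale)
    disease = DiseaseModel.from_population(hazards, config.kappa, config.carrier_prob)

    ped = Pedigree(family_id, founder_id=1)
    next_id = 1

    def new_id() -> int:
        nonlocal next_id
        i = next_id
        next_id += 1
        return i

    founder_carrier = introduce_variant(config.variant_mode, config.carrier_prob, rng)
    lo, hi = config.founder_birth_range
    founder = Individual(
        family_id=family_id,
        individual_id=new_id(),
        sex="M" if rng.random() < 0.5 else "F",
        carrier=founder_carrier,
        birth_year=int(rng.integers(lo, hi + 1)),
        relative_risk=config.kappa if founder_carrier else 1.0,
    )
    ped.add(founder)

    queue = deque([founder.individual_id])
    while queue:
        iid = queue.popleft()
        ind = ped[iid]
        gamma, a1, a2 = assign_birth_traits(rng, repro)
        state = IndividualState(
            age=0.0,
            affected=False,
            carrier=ind.carrier,
            birth_rate=gamma,
            repro_start=a1,
            repro_stop=a2,
            birth_year=ind.birth_year,
        )
        events = simulate_life(state, disease, hazards, repro, config.stop_year, rng)
        spouse_id: Optional[int] = None
        for ev in events:
            if ev.kind is EventKind.ONSET:
                ind.affected = True
                ind.onset_year = ev.year
            elif ev.kind is EventKind.DEATH:
                ind.death_year = ev.year
            elif ev.kind is EventKind.REPRODUCTION:
                if spouse_id is None:
                    spouse = Individual(
                        family_id=family_id,
                        individual_id=new_id(),
                        sex="F" if ind.sex == "M" else "M",
                        carrier=False,
                        affected=None,  # life history not modelled
                        relative_risk=None,
                    )
                    ped.add(spouse)
                    spouse_id = spouse.individual_id
                child_carrier = transmit_variant(ind.carrier, rng)
                father, mother = (
                    (iid, spouse_id) if ind.sex == "M" else (spouse_id, iid)
                )
                child = Individual(
                    family_id=family_id,
                    individual_id=new_id(),
                    sex="M" if rng.random() < 0.5 else "F",
                    father_id=father,
                    mother_id=mother,
                    carrier=child_carrier,
                    birth_year=ev.year,
                    relative_risk=config.kappa if child_carrier else 1.0,
                )
                ped.add(child)
                queue.append(child.individual_id)
    return ped
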