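"""Competing life events for a single pedigree member.

Each individual experiences three competing event processes from birth:
disease onset (non-homogeneous Poisson, hazard scaled by the relative risk
``kappa`` for carriers), death (hazard switching from the unaffected to the
affected curve at onset), and reproduction (homogeneous Poisson within a
personal reproductive span ``[a1, a2)`` at a lifetime rate drawn once at
birth).  At each step the event with the shortest waiting time occurs; the
clock restarts from the new age, which is exact because every waiting time
is (conditionally) exponential.

The lifetime birth rate ``gamma`` is Gamma(shape 2, scale 4/3) so that, for
an individual surviving the whole span unaffected, the offspring count is a
Poisson(gamma) mixed over gamma — a negative-binomial with size 2.  The
reproductive span is drawn at birth: ``a1 ~ U(16, 27)`` years and
``a2 - a1 ~ U(10, 18)`` years.  After disease onset the birth rate is
rescaled by ``f`` (default 1: unchanged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import List, Tuple

import numpy as np

from .hazards import DiseaseModel, HazardModel, invert_cumulative_hazard

__all__ = [
    "EventKind",
    "LifeEvent",
    "ReproductionModel",
    "IndividualState",
    "assign_birth_traits",
    "draw_onset_wait",
    "draw_death_wait",
    "draw_repro_wait",
    "simulate_life",
]


class EventKind(str, Enum):
    ONSET = "onset"
    REPRODUCTION = "reproduction"
    DEATH = "death"
    CENSORED = "censored"


@dataclass(frozen=True)
class LifeEvent:
    """One recorded life event: what happened, at what age, in what calendar year."""

    kind: EventKind
    age: float
    year: int


@dataclass(frozen=True)
class ReproductionModel:
    """Parameters of the Poisson–Gamma reproduction model.

    ``gamma_shape``/``gamma_scale`` parametrise the lifetime birth-rate draw;
    ``nb_size``/``nb_prob`` record the targeted negative-binomial offspring
    model; ``onset_scale`` is the post-onset birth-rate rescaling factor
    ``f`` in [0, 1].
    """

    gamma_shape: float = 2.0
    gamma_scale: float = 4.0 / 3.0
    nb_size: int = 2
    nb_prob: float = 4.0 / 7.0
    onset_scale: float = 1.0
    repro_start_range: Tuple[float, float] = (16.0, 27.0)
    repro_span_range: Tuple[float, float] = (10.0, 18.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.onset_scale <= 1.0:
            raise ValueError(f"onset_scale f must lie in [0, 1]; got {self.onset_scale}")


@dataclass
class IndividualState:
    """Mutable life-course state of one individual."""

    age: float
    affected: bool
    carrier: bool
    birth_rate: float  # lifetime rate draw gamma (births per reproductive span)
    repro_start: float  # a1, years
    repro_stop: float  # a2, years
    birth_year: int


def assign_birth_traits(rng: np.random.Generator, model: ReproductionModel) -> Tuple[float, float, float]:
    """Draw the lifetime birth rate and reproductive span assigned at birth.

    Returns ``(gamma, a1, a2)`` with ``gamma ~ Gamma(shape, scale)``,
    ``a1 ~ U(16, 27)`` and ``a2 = a1 + U(10, 18)``.
    """
    gamma = float(rng.gamma(model.gamma_shape, model.gamma_scale))
    a1 = float(rng.uniform(*model.repro_start_range))
    a2 = a1 + float(rng.uniform(*model.repro_span_range))
    return gamma, a1, a2


def draw_onset_wait(
    state: IndividualState,
    disease: DiseaseModel,
    hazards: HazardModel,
    rng: np.random.Generator,
) -> float:
    """Waiting time to disease onset from the current age, or +inf.

    The onset hazard is the baseline curve for non-carriers and ``kappa``
    times it for carriers; disease strikes at most once, so this may only be
    called while unaffected.
    """
    if state.affected:
        raise ValueError("onset wait is undefined for an already-affected individual")
    mult = disease.hazard_multiplier(state.carrier)
    return invert_cumulative_hazard(
        hazards, "onset_pop", state.age, rng.exponential(), kappa_mult=mult
    )


def draw_death_wait(
    state: IndividualState,
    hazards: HazardModel,
    rng: np.random.Generator,
) -> float:
    """Waiting time to death from the current age; always finite.

    Uses the unaffected death hazard while disease-free and the affected
    hazard after onset.  An individual whose Exp(1) target exceeds the
    remaining hazard mass dies at the final partition boundary (maximum
    modelled age).
    """
    column = "death_affected" if state.affected else "death_unaffected"
    wait = invert_cumulative_hazard(hazards, column, state.age, rng.exponential())
    if math.isinf(wait):
        return hazards.max_age - state.age
    return wait


def draw_repro_wait(
    state: IndividualState,
    model: ReproductionModel,
    rng: np.random.Generator,
) -> float:
    """Waiting time to the next reproduction event, or +inf.

    An unconditional wait ``w ~ Exp(rate)`` with
    ``rate = gamma * (f if affected else 1) / (a2 - a1)`` is drawn and then
    conditioned on the current age ``t'``:

    * ``t' < a1`` and ``a1 + w < a2``: event at age ``a1 + w`` (wait
      ``a1 + w - t'`` — the reproductive clock only runs inside the span);
    * ``t'`` in ``[a1, a2)`` and ``t' + w < a2``: residual wait ``w``;
    * otherwise no further reproduction: +inf.
    """
    scale_f = model.onset_scale if state.affected else 1.0
    rate = state.birth_rate * scale_f / (state.repro_stop - state.repro_start)
    if rate <= 0:
        return math.inf
    w = float(rng.exponential(1.0 / rate))
    t = state.age
    if t < state.repro_start:
        if state.repro_start + w < state.repro_stop:
            return state.repro_start + w - t
        return math.inf
    if t < state.repro_stop and t + w < state.repro_stop:
        return w
    return math.inf


def simulate_life(
    start: IndividualState,
    disease: DiseaseModel,
    hazards: HazardModel,
    repro: ReproductionModel,
    stop_year: int,
    rng: np.random.Generator,
) -> List[LifeEvent]:
    """Simulate all life events from ``start`` until death or the study stop year.

    At each step the three competing waiting times are drawn (onset only
    while unaffected) and the shortest wins; ties (probability zero) break
    death > onset > reproduction.  An event whose calendar year
    ``floor(birth_year + age)`` would exceed ``stop_year`` is discarded and
    the individual is recorded as censored at ``stop_year``.  Onset flips the
    disease status, switching the subsequent death hazard to the affected
    curve and rescaling the birth rate by ``f``.
    """
    state = replace(start)
    events: List[LifeEvent] = []
    while True:
        onset_w = math.inf if state.affected else draw_onset_wait(state, disease, hazards, rng)
        death_w = draw_death_wait(state, hazards, rng)
        repro_w = draw_repro_wait(state, repro, rng)
        # tie-break priority: death > onset > reproduction
        kind, wait = EventKind.DEATH, death_w
        if onset_w < wait:
            kind, wait = EventKind.ONSET, onset_w
        if repro_w < wait:
            kind, wait = EventKind.REPRODUCTION, repro_w
        new_age = state.age + wait
        year = math.floor(state.birth_year + new_age)
        if year > stop_year:
            # events earlier in the stop year may already have been recorded
            censor_age = max(float(stop_year - state.birth_year), state.age)
            events.append(LifeEvent(EventKind.CENSORED, censor_age, int(stop_year)))
            return events
        events.append(LifeEvent(kind, float(new_age), int(year)))
        state.age = new_age
        if kind is EventKind.DEATH:
            return events
        if kind is EventKind.ONSET:
            state.affected = True
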