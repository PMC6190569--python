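"""Synthetic age-specific hazard curves for development and testing.

Generates hazard tables with the qualitative shape of an adult-onset
disease: a disease hazard that is small in childhood and rises with age
(logistic ramp), and Gompertz death hazards with the affected population
dying faster than the unaffected one by a constant excess multiplier.

The default disease hazard is deliberately elevated relative to a rare
cancer so that ascertained families are produced quickly at desk scale;
every qualitative property of the simulator (effect of the relative risk
on family counts and clustering, apparent anticipation, segregation
proportions) is shape-agnostic and does not depend on the absolute rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .hazards import HazardModel

__all__ = ["SyntheticHazardSpec", "make_synthetic_hazards"]


@dataclass(frozen=True)
class SyntheticHazardSpec:
    """Parameters of the synthetic hazard curves.

    Disease onset: ``floor + (peak - floor) * logistic((age - rise_age) / rise_width)``.
    Death (unaffected): Gompertz ``rate_at_birth * exp(slope * age)``.
    Death (affected): ``excess`` times the unaffected hazard at every age.
    All rates are events per person-year; ages in years, yearly bins.
    """

    onset_floor: float = 1e-4
    onset_peak: float = 4e-3
    onset_rise_age: float = 50.0
    onset_rise_width: float = 8.0
    death_rate_at_birth: float = 1e-4
    death_gompertz_slope: float = 0.085
    affected_excess: float = 2.0
    max_age: int = 100

    def __post_init__(self) -> None:
        if self.affected_excess < 1:
            raise ValueError("affected_excess must be >= 1 (affected die no slower)")
        if min(self.onset_floor, self.onset_peak, self.death_rate_at_birth) < 0:
            raise ValueError("hazard levels must be nonnegative")
        if self.max_age < 1:
            raise ValueError("max_age must be >= 1")


def make_synthetic_hazards(
    spec: Optional[SyntheticHazardSpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> HazardModel:
    """Build a :class:`HazardModel` with yearly bins from 0 to ``max_age``.

    Deterministic given the spec; if ``rng`` is supplied, a mild lognormal
    perturbation is applied per bin (the same noise to both death columns,
    preserving affected >= unaffected).
    """
    if spec is None:
        spec = SyntheticHazardSpec()
    ages = np.arange(spec.max_age) + 0.5  # bin midpoints
    ramp = 1.0 / (1.0 + np.exp(-(ages - spec.onset_rise_age) / spec.onset_rise_width))
    onset = spec.onset_floor + (spec.onset_peak - spec.onset_floor) * ramp
    death_u = spec.death_rate_at_birth * np.exp(spec.death_gompertz_slope * ages)
    if rng is not None:
        onset = onset * np.exp(rng.normal(0.0, 0.05, size=onset.shape))
        death_u = death_u * np.exp(rng.normal(0.0, 0.05, size=death_u.shape))
    death_a = spec.affected_excess * death_u
    return HazardModel(
        partition=np.arange(spec.max_age + 1, dtype=float),
        onset_pop=onset,
        death_unaffected=death_u,
        death_affected=death_a,
    )
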