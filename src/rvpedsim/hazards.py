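"""Age-specific hazard curves and the carrier/non-carrier mixture model.

A :class:`HazardModel` holds three piecewise-constant hazard curves over a
common age partition: the population disease-onset hazard, and death hazards
for the unaffected and affected populations.  Waiting times to life events
are sampled by inverting the cumulative hazard against an Exp(1) target,
which keeps every sampler exact and closed-form-checkable.

The genetic model is a two-component mixture: a fraction ``p_c`` of the
population carries a rare variant that multiplies the baseline onset hazard
by the relative risk ``kappa``.  Given the *population* onset hazard
``lambda_onset(t)``, the sporadic (baseline) hazard is recovered as

    lambda_o(t) = lambda_onset(t) / (1 + p_c * (kappa - 1))

so that (1 - p_c) * lambda_o + kappa * p_c * lambda_o = lambda_onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HazardModel",
    "DiseaseModel",
    "validate_hazard",
    "baseline_onset",
    "cumulative_hazard",
    "invert_cumulative_hazard",
    "read_hazard_csv",
    "write_hazard_csv",
    "HAZARD_COLUMNS",
]

#: Names of the three hazard columns, in table order.
HAZARD_COLUMNS = ("onset_pop", "death_unaffected", "death_affected")


class HazardValidationError(ValueError):
    """Raised when a hazard table or partition violates the model contract."""


@dataclass(frozen=True)
class HazardModel:
    """Piecewise-constant age-specific hazards on a shared age partition.

    ``partition`` has length ``n_bins + 1``; bin ``k`` applies to ages in the
    half-open interval ``[partition[k], partition[k+1])``.  The final
    boundary is the maximum modelled age: an individual who reaches it with
    no simulated death event dies there.
    """

    partition: np.ndarray
    onset_pop: np.ndarray
    death_unaffected: np.ndarray
    death_affected: np.ndarray

    def __post_init__(self) -> None:
        part = np.asarray(self.partition, dtype=float)
        object.__setattr__(self, "partition", part)
        if part.ndim != 1 or part.size < 2:
            raise HazardValidationError("partition must be a 1-d sequence of >= 2 ages")
        if part[0] != 0:
            raise HazardValidationError("partition must start at 0")
        if not np.all(np.diff(part) > 0):
            raise HazardValidationError("partition must be strictly increasing")
        n_bins = part.size - 1
        for name in HAZARD_COLUMNS:
            col = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, col)
            if col.shape != (n_bins,):
                raise HazardValidationError(
                    f"column {name!r} has {col.size} entries; expected {n_bins} "
                    f"(one per age bin)"
                )
            if not np.all(np.isfinite(col)):
                bad = int(np.flatnonzero(~np.isfinite(col))[0])
                raise HazardValidationError(f"column {name!r} has a non-finite rate at row {bad}")
            if np.any(col < 0):
                bad = int(np.flatnonzero(col < 0)[0])
                raise HazardValidationError(f"column {name!r} has a negative rate at row {bad}")

    @property
    def n_bins(self) -> int:
        return self.partition.size - 1

    @property
    def max_age(self) -> float:
        """Maximum modelled age (final partition boundary)."""
        return float(self.partition[-1])

    def rates(self, column: str) -> np.ndarray:
        if column not in HAZARD_COLUMNS:
            raise KeyError(f"unknown hazard column {column!r}; expected one of {HAZARD_COLUMNS}")
        return getattr(self, column)


def validate_hazard(table, partition) -> HazardModel:
    """Build a :class:`HazardModel` from a raw 3-column table and an age partition.

    ``table`` may be a DataFrame (columns taken in order) or an array of
    shape ``(n_bins, 3)``.  Rejects non-monotone partitions, negative rates
    and length mismatches with a message naming the offending column.
    """
    if isinstance(table, pd.DataFrame):
        arr = table.to_numpy(dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise HazardValidationError(
            f"hazard table must have exactly 3 columns "
            f"({', '.join(HAZARD_COLUMNS)}); got shape {arr.shape}"
        )
    return HazardModel(
        partition=np.asarray(partition, dtype=float),
        onset_pop=arr[:, 0],
        death_unaffected=arr[:, 1],
        death_affected=arr[:, 2],
    )


def baseline_onset(pop_hazard, kappa: float, carrier_prob: float) -> np.ndarray:
    """Sporadic (non-carrier) onset hazard implied by the population hazard.

    Divides each per-bin population rate by ``1 + p_c * (kappa - 1)``.  The
    carrier hazard is ``kappa`` times the result.
    """
    if kappa < 1:
        raise ValueError(f"kappa must be >= 1; got {kappa}")
    if not 0 <= carrier_prob <= 1:
        raise ValueError(f"carrier_prob must lie in [0, 1]; got {carrier_prob}")
    rates = np.asarray(pop_hazard, dtype=float)
    return rates / (1.0 + carrier_prob * (kappa - 1.0))


@dataclass(frozen=True)
class DiseaseModel:
    """Genetic disease model: relative risk, carrier probability, baseline hazard."""

    kappa: float
    carrier_prob: float
    onset_baseline: np.ndarray = field(repr=False)

    @classmethod
    def from_population(cls, hazards: HazardModel, kappa: float, carrier_prob: float) -> "DiseaseModel":
        base = baseline_onset(hazards.onset_pop, kappa, carrier_prob)
        return cls(kappa=float(kappa), carrier_prob=float(carrier_prob), onset_baseline=base)

    def hazard_multiplier(self, carrier: bool) -> float:
        """Factor applied to the *population* onset column to get the
        individual's onset hazard: kappa (carrier) or 1 (non-carrier),
        divided by the mixture normaliser 1 + p_c (kappa - 1)."""
        denom = 1.0 + self.carrier_prob * (self.kappa - 1.0)
        return (self.kappa if carrier else 1.0) / denom


def _clipped_bin_widths(partition: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # width of the intersection of each bin with [lo, hi)
    left = np.clip(partition[:-1], lo, hi)
    right = np.clip(partition[1:], lo, hi)
    return right - left


def cumulative_hazard(
    model: HazardModel,
    column: str,
    from_age: float,
    to_age: float,
    kappa_mult: float = 1.0,
) -> float:
    """Exact piecewise-constant integral of a hazard column over ``[from_age, to_age)``.

    The result is multiplied by ``kappa_mult`` and is additive over abutting
    age intervals.
    """
    if not 0 <= from_age <= to_age:
        raise ValueError(f"require 0 <= from_age <= to_age; got [{from_age}, {to_age}]")
    if to_age > model.max_age:
        raise ValueError(f"to_age {to_age} exceeds the final partition boundary {model.max_age}")
    widths = _clipped_bin_widths(model.partition, from_age, to_age)
    return float(kappa_mult * np.dot(model.rates(column), widths))


def invert_cumulative_hazard(
    model: HazardModel,
    column: str,
    from_age: float,
    target: float,
    kappa_mult: float = 1.0,
) -> float:
    """Smallest waiting time ``w`` with cumulative hazard from ``from_age`` equal to ``target``.

    Returns ``math.inf`` when the total remaining cumulative hazard up to the
    final partition boundary is less than ``target``.  With ``target`` an
    Exp(1) draw this is the standard inversion sampler for a
    non-homogeneous Poisson process with piecewise-constant intensity.
    """
    if target < 0:
        raise ValueError(f"target must be >= 0; got {target}")
    if not 0 <= from_age <= model.max_age:
        raise ValueError(f"from_age {from_age} outside [0, {model.max_age}]")
    if target == 0:
        return 0.0
    rates = model.rates(column) * kappa_mult
    # per-bin hazard mass above from_age
    widths = _clipped_bin_widths(model.partition, from_age, model.max_age)
    masses = rates * widths
    cum = np.cumsum(masses)
    if cum[-1] < target:
        return math.inf
    k = int(np.searchsorted(cum, target, side="left"))
    prev = cum[k - 1] if k > 0 else 0.0
    # rates[k] > 0 here: k is the first bin whose cumulative mass reaches target
    bin_start = max(float(model.partition[k]), from_age)
    return bin_start + (target - prev) / rates[k] - from_age


# ---------------------------------------------------------------------------
# Hazard CSV interface
# ---------------------------------------------------------------------------

_CSV_HEADER = ["age_lo", "onset_pop", "death_unaffected", "death_affected"]


def read_hazard_csv(path, max_age: float = 100.0) -> HazardModel:
    """Read a hazard table from CSV (header ``age_lo,onset_pop,death_unaffected,death_affected``).

    The age partition is reconstructed from the ``age_lo`` column plus
    ``max_age`` as the final boundary.  Strict: rejects missing columns,
    non-monotone ages and a last bin that would be empty.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_HEADER if c not in df.columns]
    if missing:
        raise HazardValidationError(f"hazard CSV {path} missing column(s): {', '.join(missing)}")
    age_lo = df["age_lo"].to_numpy(dtype=float)
    if age_lo.size == 0:
        raise HazardValidationError(f"hazard CSV {path} has no rows")
    if age_lo[-1] >= max_age:
        raise HazardValidationError(
            f"last age_lo ({age_lo[-1]}) must be below max_age ({max_age})"
        )
    partition = np.append(age_lo, max_age)
    return validate_hazard(df[list(HAZARD_COLUMNS)], partition)


def write_hazard_csv(model: HazardModel, path) -> None:
    """Write a :class:`HazardModel` in the CSV dialect read by :func:`read_hazard_csv`."""
    df = pd.DataFrame(
        {
            "age_lo": model.partition[:-1],
            "onset_pop": model.onset_pop,
            "death_unaffected": model.death_unaffected,
            "death_affected": model.death_affected,
        }
    )
    df.to_csv(path, index=False)
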