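"""Effective dose and stochastic-risk projections from organ doses.

Effective dose is the tissue-weighted sum E = Σ W_T·H_T over the named
organs, plus a remainder compartment.  The remainder enters the
effective dose through the **mean** of the remainder-organ doses (one
compartment at weight 0.05), while the fatal-cancer risk applies the
remainder coefficient to the **sum** of remainder doses.  The asymmetry
was reverse-engineered from the reference results this package
reproduces and both rules are explicit arguments, so either side can be
overridden.

Risk projections are the flat NCRP-116 coefficient products: expected
fatal-cancer cases = H_T[Sv] × coefficient[10⁻² Sv⁻¹] × population, and
analogously for heritable (genetic) effects on the gonad dose.  No
age/sex-specific lifetime-attributable-risk modelling is attempted.

Uncertainty propagation is first-order and treats doses derived from
the same measurement point (distance bin) as fully correlated, doses
from different bins as independent; coefficients carry no uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .composite_organs import partition_remainder
from .dosimetry import OrganDose
from .reference_data import DoseCoefficients, ValidationError, organ_key

__all__ = [
    "EffectiveDoseResult",
    "RiskResult",
    "effective_dose",
    "organ_cancer_risk",
    "total_cancer_risk",
    "genetic_effects",
    "propagate_uncertainty",
]

REMAINDER_KEY = "remainder"


@dataclass(frozen=True)
class EffectiveDoseResult:
    """Effective dose with per-compartment contributions.

    ``contributions`` maps each named organ plus the remainder
    compartment to W_T·H_T in mSv; ``shares`` to its percentage of the
    total.
    """

    effective_dose_mSv: float
    contributions: Mapping[str, float]
    shares: Mapping[str, float]
    sd_mSv: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.contributions.values())
        if abs(total - self.effective_dose_mSv) > 1e-9 * max(1.0, abs(total)):
            raise ValidationError("contributions do not sum to the effective dose")


@dataclass(frozen=True)
class RiskResult:
    """Expected stochastic-effect cases in a population.

    All case counts refer to ``population_size`` persons each receiving
    the assessed organ doses.
    """

    per_organ_cases_per_million: Mapping[str, float]
    total_cases_per_million: float
    genetic_cases_per_million: float | None = None
    population_size: float = 1e6
    sd_total: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.per_organ_cases_per_million.values()):
            raise ValidationError("negative per-organ risk")
        total = sum(self.per_organ_cases_per_million.values())
        if abs(total - self.total_cases_per_million) > 1e-9 * max(1.0, abs(total)):
            raise ValidationError("per-organ risks do not sum to the total")


def _total_mSv(dose: OrganDose | float) -> float:
    return dose.total if isinstance(dose, OrganDose) else float(dose)


def effective_dose(
    organ_doses: Mapping[str, OrganDose | float],
    coefficients: DoseCoefficients,
    remainder_rule: Literal["mean", "sum"] = "mean",
) -> EffectiveDoseResult:
    """E = Σ W_T·H_T over named organs plus the remainder compartment.

    ``organ_doses`` maps organ names to :class:`OrganDose` or bare
    totals in mSv.  Every named organ in the coefficient table must be
    dosed.
    """
    doses = {organ_key(k): _total_mSv(v) for k, v in organ_doses.items()}
    missing = sorted(set(coefficients.tissue_weights) - set(doses))
    if missing:
        raise ValidationError(f"named organs without a dose: {missing}")
    wrapped = {k: OrganDose(organ_name=k, per_gray=0.0, total=v) for k, v in doses.items()}
    named, remainder = partition_remainder(wrapped, coefficients)

    contributions = {
        k: coefficients.tissue_weights[k] * named[k].total for k in named
    }
    if remainder_rule not in ("mean", "sum"):
        raise ValidationError(f"unknown remainder rule {remainder_rule!r}")
    if remainder:
        rem_doses = [d.total for d in remainder.values()]
        pooled = float(np.mean(rem_doses)) if remainder_rule == "mean" else float(np.sum(rem_doses))
        contributions[REMAINDER_KEY] = coefficients.remainder_weight * pooled
    total = sum(contributions.values())
    shares = {
        k: (100.0 * v / total if total > 0 else 0.0) for k, v in contributions.items()
    }
    return EffectiveDoseResult(
        effective_dose_mSv=total, contributions=contributions, shares=shares
    )


def organ_cancer_risk(
    h_t_mSv: float, coefficient_1e2_per_sv: float, population: float = 1e6
) -> float:
    """Expected fatal-cancer cases from one organ dose.

    cases = H_T[Sv] × (coefficient × 10⁻² Sv⁻¹) × population.
    """
    if h_t_mSv < 0 or coefficient_1e2_per_sv < 0 or population < 0:
        raise ValidationError("dose, coefficient and population must be >= 0")
    return (h_t_mSv / 1000.0) * (coefficient_1e2_per_sv * 1e-2) * population


def total_cancer_risk(
    organ_doses: Mapping[str, OrganDose | float],
    coefficients: DoseCoefficients,
    remainder_rule: Literal["sum", "mean"] = "sum",
    population: float = 1e6,
) -> RiskResult:
    """Fatal-cancer risk per organ and in total.

    Named organs use their own coefficients; the remainder compartment
    applies the remainder coefficient to the pooled (by default summed)
    remainder dose.
    """
    doses = {organ_key(k): _total_mSv(v) for k, v in organ_doses.items()}
    missing = sorted(set(coefficients.tissue_weights) - set(doses))
    if missing:
        raise ValidationError(f"named organs without a dose: {missing}")
    wrapped = {k: OrganDose(organ_name=k, per_gray=0.0, total=v) for k, v in doses.items()}
    named, remainder = partition_remainder(wrapped, coefficients)

    per_organ = {
        k: organ_cancer_risk(named[k].total, coefficients.risk_coefficients[k], population)
        for k in named
    }
    if remainder_rule not in ("mean", "sum"):
        raise ValidationError(f"unknown remainder rule {remainder_rule!r}")
    if remainder:
        rem_doses = [d.total for d in remainder.values()]
        pooled = float(np.sum(rem_doses)) if remainder_rule == "sum" else float(np.mean(rem_doses))
        per_organ[REMAINDER_KEY] = organ_cancer_risk(
            pooled, coefficients.remainder_risk_coefficient, population
        )
    genetic = None
    if "gonads" in doses:
        genetic = genetic_effects(
            doses["gonads"], coefficients.genetic_coefficient, population
        )
    return RiskResult(
        per_organ_cases_per_million=per_organ,
        total_cases_per_million=sum(per_organ.values()),
        genetic_cases_per_million=genetic,
        population_size=population,
    )


def genetic_effects(
    gonad_dose_mSv: float, genetic_coefficient_1e2_per_sv: float = 1.00,
    population: float = 1e6,
) -> float:
    """Expected heritable-effect cases from the gonad dose."""
    return organ_cancer_risk(gonad_dose_mSv, genetic_coefficient_1e2_per_sv, population)


def _grouped_linear_sd(items: list[tuple[float, float, object]]) -> float:
    """sd of Σ w·x for x grouped by label: full correlation within a
    group, independence across groups (None labels are each their own
    group)."""
    groups: dict[object, float] = {}
    independent = 0.0
    for weight, sd, label in items:
        if label is None:
            independent += (weight * sd) ** 2
        else:
            groups[label] = groups.get(label, 0.0) + weight * sd
    return float(np.sqrt(independent + sum(g**2 for g in groups.values())))


def propagate_uncertainty(
    organ_doses: Mapping[str, OrganDose],
    coefficients: DoseCoefficients,
    effective_remainder_rule: Literal["mean", "sum"] = "mean",
    risk_remainder_rule: Literal["sum", "mean"] = "sum",
    population: float = 1e6,
) -> dict[str, float]:
    """First-order sd of the effective dose and the total cancer risk.

    Doses sharing a ``bin_distance_cm`` are treated as fully correlated
    (they scale with the same measurement); doses with distinct or
    missing bins are independent.  Coefficient uncertainty is zero.
    """
    doses = {organ_key(k): v for k, v in organ_doses.items()}
    named, remainder = partition_remainder(doses, coefficients)
    n_rem = len(remainder)

    eff_items: list[tuple[float, float, object]] = []
    risk_items: list[tuple[float, float, object]] = []
    for k, d in named.items():
        eff_items.append((coefficients.tissue_weights[k], d.sd_total, d.bin_distance_cm))
        cases_per_mSv = coefficients.risk_coefficients[k] * 1e-2 * population / 1000.0
        risk_items.append((cases_per_mSv, d.sd_total, d.bin_distance_cm))
    for k, d in remainder.items():
        w_eff = coefficients.remainder_weight * (
            1.0 / n_rem if effective_remainder_rule == "mean" else 1.0
        )
        eff_items.append((w_eff, d.sd_total, d.bin_distance_cm))
        w_risk = coefficients.remainder_risk_coefficient * 1e-2 * population / 1000.0
        if risk_remainder_rule == "mean":
            w_risk /= n_rem
        risk_items.append((w_risk, d.sd_total, d.bin_distance_cm))
    return {
        "effective_dose_sd_mSv": _grouped_linear_sd(eff_items),
        "total_risk_sd_cases": _grouped_linear_sd(risk_items),
    }
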