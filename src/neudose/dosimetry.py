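"""From H*(10) at the patient table to per-organ neutron equivalent dose.

The rem-meter cannot sit inside a phantom, so the measured ambient dose
equivalent is transferred to each organ in two steps:

1. **Distance bin assignment** — the out-of-field neutron spectrum varies
   slowly with lateral distance, so a small number of measurement points
   stand in for whole distance bins (by default the 20-cm point for
   organs 5-40 cm from the central axis and the 60-cm point for
   40-80 cm, organs beyond 80 cm clamping to the far bin).
2. **Depth correction** — multiply by the ratio of the neutron
   depth-dose curve at organ depth to its value at the 1-cm reference
   depth where H*(10) is defined.

The per-Gy organ dose times the prescribed photon dose gives the
course total.  ``rounding_mode="paper"`` rounds the per-Gy dose to two
decimals (half-even) before the course multiplication, matching how the
source tables were evidently produced; ``"precise"`` (default) keeps
full precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np

from .reference_data import (
    DepthDoseCurve,
    MeasurementPoint,
    MeasurementSet,
    OrganGeometry,
    TreatmentPrescription,
    ValidationError,
    round_half_even,
)

__all__ = [
    "DistanceBin",
    "DistanceBinRule",
    "OrganDose",
    "DEFAULT_BIN_RULE",
    "interpolate_depth_dose",
    "depth_correction_factor",
    "assign_distance_bin",
    "organ_equivalent_dose",
    "classify_depth",
    "depth_class_means",
]

Scheme = Literal["linear", "log-linear"]
RoundingMode = Literal["paper", "precise"]

DEPTH_CLASSES = ("surface", "middle", "deep", "unclassified")


# --- depth-dose interpolation ----------------------------------------------


def interpolate_depth_dose(
    curve: DepthDoseCurve, depth_cm: float, scheme: Scheme = "linear"
) -> float:
    """Dose density at ``depth_cm``, interpolating the tabulated curve.

    ``linear`` interpolates the dose density directly; ``log-linear``
    interpolates its logarithm (exact for exponentially attenuating
    dose, which the tabulated curve approximates).  Both are exact at
    grid points.  Depths shallower than the grid are refused — the curve
    says nothing about the build-up region — while depths beyond the
    deepest row clamp to the last value with a warning.
    """
    depths = curve.depths_cm
    if depth_cm < depths[0]:
        raise ValidationError(
            f"depth {depth_cm} cm is above the tabulated range "
            f"(first grid depth {depths[0]} cm); no surface extrapolation"
        )
    if depth_cm > depths[-1]:
        warnings.warn(
            f"depth {depth_cm} cm beyond the tabulated maximum {depths[-1]} cm; "
            "clamping to the deepest tabulated value",
            stacklevel=2,
        )
        depth_cm = float(depths[-1])
    if scheme == "linear":
        return float(np.interp(depth_cm, depths, curve.dose_density))
    if scheme == "log-linear":
        return float(np.exp(np.interp(depth_cm, depths, np.log(curve.dose_density))))
    raise ValidationError(f"unknown interpolation scheme {scheme!r}")


def depth_correction_factor(
    curve: DepthDoseCurve, depth_cm: float, scheme: Scheme = "linear"
) -> float:
    """Ratio of dose density at organ depth to that at the reference depth."""
    ref = interpolate_depth_dose(curve, curve.reference_depth_cm, scheme)
    return interpolate_depth_dose(curve, depth_cm, scheme) / ref


# --- distance bins ----------------------------------------------------------


@dataclass(frozen=True)
class DistanceBin:
    lower_cm: float
    upper_cm: float
    representative_cm: float


@dataclass(frozen=True)
class DistanceBinRule:
    """Maps lateral organ distance to the measurement point representing it.

    Bins must be ordered and non-overlapping.  The first bin is closed
    on both ends; later bins are half-open (lower, upper].  Distances
    beyond the last bin follow ``out_of_range_policy``: ``"clamp"`` uses
    the last bin, ``"error"`` refuses.  Distances below the first bin
    are always an error — organs inside or at the edge of the treatment
    field are outside this model's validity.
    """

    bins: tuple[DistanceBin, ...]
    out_of_range_policy: Literal["clamp", "error"] = "clamp"

    def __post_init__(self) -> None:
        object.__setattr__(self, "bins", tuple(self.bins))
        if not self.bins:
            raise ValidationError("bin rule needs at least one bin")
        for b in self.bins:
            if not b.lower_cm < b.upper_cm:
                raise ValidationError(f"bin {b} has lower >= upper")
            if not b.lower_cm <= b.representative_cm <= b.upper_cm:
                raise ValidationError(f"representative distance of {b} outside the bin")
        for a, b in zip(self.bins, self.bins[1:]):
            if b.lower_cm < a.upper_cm:
                raise ValidationError(f"bins {a} and {b} overlap or are out of order")
        if self.out_of_range_policy not in ("clamp", "error"):
            raise ValidationError(
                f"unknown out_of_range_policy {self.out_of_range_policy!r}"
            )

    def validate_against(self, measurements: MeasurementSet) -> list[str]:
        """Problems preventing this rule from being used with ``measurements``."""
        problems = []
        for b in self.bins:
            try:
                measurements.point_at(b.representative_cm)
            except ValidationError:
                problems.append(
                    f"bin [{b.lower_cm}, {b.upper_cm}] cm: no measurement at its "
                    f"representative distance {b.representative_cm} cm"
                )
        return problems


#: Default rule: [5, 40] cm served by the 20-cm point, (40, 80] cm by the
#: 60-cm point, farther organs clamped to the far bin.
DEFAULT_BIN_RULE = DistanceBinRule(
    bins=(DistanceBin(5.0, 40.0, 20.0), DistanceBin(40.0, 80.0, 60.0)),
    out_of_range_policy="clamp",
)


def assign_distance_bin(
    rule: DistanceBinRule, measurements: MeasurementSet, distance_cm: float
) -> MeasurementPoint:
    """Measurement point representing an organ at ``distance_cm``."""
    first = rule.bins[0]
    if distance_cm < first.lower_cm:
        raise ValidationError(
            f"distance {distance_cm} cm is inside the treatment-field margin "
            f"(< {first.lower_cm} cm); the out-of-field model does not apply"
        )
    for i, b in enumerate(rule.bins):
        lower_ok = distance_cm >= b.lower_cm if i == 0 else distance_cm > b.lower_cm
        if lower_ok and distance_cm <= b.upper_cm:
            return measurements.point_at(b.representative_cm)
    if rule.out_of_range_policy == "clamp":
        return measurements.point_at(rule.bins[-1].representative_cm)
    raise ValidationError(
        f"distance {distance_cm} cm beyond the last bin "
        f"(> {rule.bins[-1].upper_cm} cm) and policy is 'error'"
    )


# --- per-organ dose ---------------------------------------------------------


@dataclass(frozen=True)
class OrganDose:
    """Neutron equivalent dose of one organ (or composite compartment).

    ``per_gray`` is mSv per Gy of prescribed photon dose (already
    rounded in paper mode, so ``total == per_gray × prescribed dose``
    holds in the active rounding mode); ``total``/``sd_total`` are mSv
    over the course.  ``bin_distance_cm`` records which measurement
    point the dose derives from (None for composites mixing bins).
    """

    organ_name: str
    per_gray: float
    total: float
    sd_total: float = 0.0
    bin_distance_cm: float | None = None
    depth_factor: float = 1.0
    depth_class: str = "unclassified"

    def __post_init__(self) -> None:
        if self.per_gray < 0 or self.total < 0 or self.sd_total < 0:
            raise ValidationError(f"{self.organ_name}: negative dose or sd")
        if not self.depth_factor > 0:
            raise ValidationError(f"{self.organ_name}: depth_factor must be > 0")
        if self.depth_class not in DEPTH_CLASSES:
            raise ValidationError(f"unknown depth class {self.depth_class!r}")


def classify_depth(depth_cm: float) -> str:
    """Depth class: surface [0, 5], middle (5, 10], deep (10, 15] cm.

    Depths beyond 15 cm fall outside the stated classes and are
    ``"unclassified"``.
    """
    if depth_cm < 0:
        raise ValidationError(f"depth must be >= 0, got {depth_cm}")
    if depth_cm <= 5.0:
        return "surface"
    if depth_cm <= 10.0:
        return "middle"
    if depth_cm <= 15.0:
        return "deep"
    return "unclassified"


def organ_equivalent_dose(
    organ: OrganGeometry,
    measurements: MeasurementSet,
    curve: DepthDoseCurve,
    rule: DistanceBinRule = DEFAULT_BIN_RULE,
    prescription: TreatmentPrescription | None = None,
    scheme: Scheme = "linear",
    rounding_mode: RoundingMode = "precise",
) -> OrganDose:
    """Neutron equivalent dose of one organ.

    per-Gy dose = H*(10) of the organ's distance bin × depth correction
    factor at the organ's depth.  The course total multiplies by the
    prescribed photon dose; its uncertainty scales with the relative
    standard deviation of the bin measurement.
    """
    point = assign_distance_bin(rule, measurements, organ.distance_cm)
    factor = depth_correction_factor(curve, organ.depth_cm, scheme)
    per_gray = point.h10_per_gray * factor
    if rounding_mode == "paper":
        per_gray = round_half_even(per_gray, 2)
    elif rounding_mode != "precise":
        raise ValidationError(f"unknown rounding mode {rounding_mode!r}")
    dose = prescription.prescribed_dose_gray if prescription else 1.0
    total = per_gray * dose
    sd_total = total * (point.sd_per_gray / point.h10_per_gray)
    return OrganDose(
        organ_name=organ.organ_name,
        per_gray=per_gray,
        total=total,
        sd_total=sd_total,
        bin_distance_cm=point.distance_cm,
        depth_factor=factor,
        depth_class=classify_depth(organ.depth_cm),
    )


def organ_equivalent_doses(
    organs: Mapping[str, OrganGeometry] | Iterable[OrganGeometry],
    measurements: MeasurementSet,
    curve: DepthDoseCurve,
    rule: DistanceBinRule = DEFAULT_BIN_RULE,
    prescription: TreatmentPrescription | None = None,
    scheme: Scheme = "linear",
    rounding_mode: RoundingMode = "precise",
) -> dict[str, OrganDose]:
    """Vector version of :func:`organ_equivalent_dose`, keyed by organ key."""
    geoms = organs.values() if isinstance(organs, Mapping) else organs
    out: dict[str, OrganDose] = {}
    for geo in geoms:
        dose = organ_equivalent_dose(
            geo, measurements, curve, rule, prescription, scheme, rounding_mode
        )
        out[geo.organ_name.strip().lower()] = dose
    return out


def depth_class_means(
    doses: Iterable[OrganDose], decimals: int | None = None
) -> dict[str, float]:
    """Arithmetic mean per-Gy dose per depth class.

    Unclassified organs are excluded from the three stated classes and
    reported under their own ``"unclassified"`` key.  ``decimals`` (if
    given) half-even-rounds each mean, matching tabulated summaries.
    """
    doses = list(doses)
    if not doses:
        raise ValidationError("depth_class_means needs at least one organ dose")
    out: dict[str, float] = {}
    for cls in DEPTH_CLASSES:
        values = [d.per_gray for d in doses if d.depth_class == cls]
        if values:
            mean = float(np.mean(values))
            out[cls] = round_half_even(mean, decimals) if decimals is not None else mean
    return out
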