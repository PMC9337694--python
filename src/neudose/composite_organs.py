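"""Doses for organs that cannot be located directly in the geometry table.

Three tissues need special handling:

* **Skin** is superficial and distributed, so its dose is the plain
  average of the out-of-field H*(10) measurements (20- and 60-cm
  points), with no depth correction; the sliver of skin inside the
  treatment field is ignored.
* **Red bone marrow** is distributed over the skeleton.  Each skeletal
  region borrows the dose of a surrogate organ at a comparable position
  (head→brain, upper limb-girdle→breast, sternum/ribs→heart,
  vertebrae→cord, sacrum/lower girdle→femoral head) and the regional
  doses are combined with the active-marrow fractions of a 40-year-old
  male.  The printed fractions sum to 0.877, not 1; ``"as-printed"``
  uses them verbatim (default), ``"renormalized"`` rescales to unit sum.
* **Bone surface** is the unweighted mean over the six non-head
  skeletal regions, each region counted once even where two regions
  share a surrogate.

The module also splits an organ-dose table into the named-W_T and
remainder compartments used by the risk stage.
"""

from __future__ import annotations

from typing import Literal, Mapping

from .dosimetry import DistanceBinRule, DEFAULT_BIN_RULE, OrganDose
from .reference_data import (
    DoseCoefficients,
    MeasurementSet,
    TreatmentPrescription,
    ValidationError,
    canonical_name,
    organ_key,
)

__all__ = [
    "DEFAULT_REGION_MAP",
    "MARROW_REGIONS",
    "BONE_SURFACE_REGIONS",
    "skin_dose",
    "red_marrow_dose",
    "bone_surface_dose",
    "partition_remainder",
    "apply_overrides",
]

MARROW_REGIONS = (
    "head",
    "upper limb-girdle",
    "sternum",
    "ribs",
    "vertebrae",
    "sacrum",
    "lower girdle",
)

#: Six regions entering the bone-surface mean (head excluded).
BONE_SURFACE_REGIONS = MARROW_REGIONS[1:]

#: Skeletal region -> surrogate organ whose dose represents it.
DEFAULT_REGION_MAP: dict[str, str] = {
    "head": "brain",
    "upper limb-girdle": "breast",
    "sternum": "heart",
    "ribs": "heart",
    "vertebrae": "cord",
    "sacrum": "femoral head",
    "lower girdle": "femoral head",
}


def skin_dose(
    measurements: MeasurementSet,
    rule: DistanceBinRule = DEFAULT_BIN_RULE,
    prescription: TreatmentPrescription | None = None,
) -> OrganDose:
    """Skin dose: mean H*(10) over the bin representative points.

    No depth correction and no per-Gy rounding before the course
    multiplication; the two measurement points are treated as
    independent for the uncertainty.
    """
    points = [measurements.point_at(b.representative_cm) for b in rule.bins]
    per_gray = sum(p.h10_per_gray for p in points) / len(points)
    sd_per_gray = (sum(p.sd_per_gray**2 for p in points) ** 0.5) / len(points)
    dose = prescription.prescribed_dose_gray if prescription else 1.0
    return OrganDose(
        organ_name="Skin",
        per_gray=per_gray,
        total=per_gray * dose,
        sd_total=sd_per_gray * dose,
        bin_distance_cm=None,
        depth_factor=1.0,
        depth_class="surface",
    )


def _surrogate(
    organ_doses: Mapping[str, OrganDose], region: str, region_map: Mapping[str, str]
) -> OrganDose:
    try:
        surrogate = region_map[region]
    except KeyError:
        raise ValidationError(f"skeletal region {region!r} has no surrogate organ")
    try:
        return organ_doses[organ_key(surrogate)]
    except KeyError:
        raise ValidationError(
            f"surrogate organ {surrogate!r} for skeletal region {region!r} "
            "is missing from the organ dose table"
        )


def red_marrow_dose(
    organ_doses: Mapping[str, OrganDose],
    marrow_distribution: Mapping[str, float],
    region_map: Mapping[str, str] = DEFAULT_REGION_MAP,
    normalization: Literal["as-printed", "renormalized"] = "as-printed",
) -> OrganDose:
    """Red bone-marrow dose: marrow-fraction-weighted sum of regional doses."""
    weights = {r: float(marrow_distribution[r]) for r in marrow_distribution}
    if not weights:
        raise ValidationError("marrow distribution is empty")
    if normalization == "renormalized":
        s = sum(weights.values())
        weights = {r: w / s for r, w in weights.items()}
    elif normalization != "as-printed":
        raise ValidationError(f"unknown marrow normalization {normalization!r}")
    per_gray = total = sd = 0.0
    for region, w in weights.items():
        d = _surrogate(organ_doses, region, region_map)
        per_gray += w * d.per_gray
        total += w * d.total
        sd += w * d.sd_total  # conservative: fully correlated surrogates
    return OrganDose(
        organ_name="Bone marrow",
        per_gray=per_gray,
        total=total,
        sd_total=sd,
        bin_distance_cm=None,
        depth_factor=1.0,
        depth_class="unclassified",
    )


def bone_surface_dose(
    organ_doses: Mapping[str, OrganDose],
    region_map: Mapping[str, str] = DEFAULT_REGION_MAP,
    regions: tuple[str, ...] = BONE_SURFACE_REGIONS,
) -> OrganDose:
    """Bone-surface dose: unweighted mean over the six skeletal regions."""
    if not regions:
        raise ValidationError("bone_surface_dose needs at least one region")
    doses = [_surrogate(organ_doses, r, region_map) for r in regions]
    n = len(doses)
    return OrganDose(
        organ_name="Bone surface",
        per_gray=sum(d.per_gray for d in doses) / n,
        total=sum(d.total for d in doses) / n,
        sd_total=sum(d.sd_total for d in doses) / n,
        bin_distance_cm=None,
        depth_factor=1.0,
        depth_class="unclassified",
    )


def partition_remainder(
    organ_doses: Mapping[str, OrganDose], coefficients: DoseCoefficients
) -> tuple[dict[str, OrganDose], dict[str, OrganDose]]:
    """Split doses into (named-W_T compartment, remainder compartment).

    Every organ lands in exactly one compartment.  When the coefficient
    table declares its remainder membership explicitly, an organ found
    in neither list is an error rather than silently absorbed.
    """
    named: dict[str, OrganDose] = {}
    remainder: dict[str, OrganDose] = {}
    for key, dose in organ_doses.items():
        key = organ_key(key)
        if key in coefficients.tissue_weights:
            named[key] = dose
        elif (
            coefficients.remainder_organs is None
            or key in coefficients.remainder_organs
        ):
            remainder[key] = dose
        else:
            raise ValidationError(
                f"organ {dose.organ_name!r} appears in neither the named-W_T "
                "table nor the declared remainder organs"
            )
    return named, remainder


def apply_overrides(
    organ_doses: Mapping[str, OrganDose],
    overrides: Mapping[str, tuple[float, float]],
    prescription: TreatmentPrescription | None = None,
) -> dict[str, OrganDose]:
    """Replace computed organ totals with externally supplied values.

    Used to inject literature organ-dose tables (e.g. values whose
    derivation the source does not state) before the risk stage.  The
    per-Gy dose is rescaled consistently with the prescription.
    """
    dose_gy = prescription.prescribed_dose_gray if prescription else 1.0
    out = dict(organ_doses)
    for key, (total, sd) in overrides.items():
        key = organ_key(key)
        old = out.get(key)
        out[key] = OrganDose(
            organ_name=old.organ_name if old else canonical_name(key),
            per_gray=total / dose_gy,
            total=total,
            sd_total=sd,
            bin_distance_cm=None,
            depth_factor=old.depth_factor if old else 1.0,
            depth_class=old.depth_class if old else "unclassified",
        )
    return out
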