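"""Typed reference tables for out-of-field neutron dosimetry.

This module houses the small experimental and literature tables the
pipeline runs on:

* a measurement set of neutron ambient dose equivalent H*(10) per Gy of
  delivered photon dose, indexed by horizontal distance from the
  isocenter (rem-meter readings at the patient table);
* a neutron depth-dose curve (absorbed dose density vs tissue depth),
  used only as a ratio to transfer the surface-referenced H*(10) to
  organ depth;
* an organ geometry table (horizontal distance from the beam central
  axis and depth below the body surface, per organ);
* NCRP-116 dose/risk coefficients: tissue weighting factors W_T,
  fatal-cancer risk coefficients, the gonad genetic-effects coefficient,
  and the active red-bone-marrow skeletal distribution of a 40-year-old
  male;
* the treatment prescription (total photon dose and fraction size).

Everything is a plain frozen dataclass with eager validation, plus CSV
readers/writers and ``paper_fixtures()`` which returns in-memory copies
of the bundled reference tables (shipped as versioned CSV files under
``neudose/data`` so users can substitute e.g. ICRP-103 coefficients
without code changes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SchemaError",
    "MeasurementPoint",
    "MeasurementSet",
    "DepthDoseCurve",
    "OrganGeometry",
    "DoseCoefficients",
    "TreatmentPrescription",
    "canonical_name",
    "round_half_even",
    "load_measurement_set",
    "write_measurement_set",
    "load_depth_dose_curve",
    "write_depth_dose_curve",
    "load_organ_geometry",
    "write_organ_geometry",
    "load_coefficients",
    "load_marrow_distribution",
    "load_organ_dose_override",
    "paper_fixtures",
    "data_path",
]


class ValidationError(ValueError):
    """An input table violates a stated invariant."""


class SchemaError(ValidationError):
    """An input file is missing required columns."""


# --- organ naming -----------------------------------------------------------

#: Canonical spellings used in reports; matching is case-insensitive after
#: trimming, so "thyroid", " Thyroid " and "THYROID" all resolve here.
CANONICAL_ORGANS = (
    "Brain",
    "Salivary glands",
    "Thyroid",
    "Esophagus",
    "Breast",
    "Lung",
    "Cord",
    "Heart",
    "Stomach",
    "Spleen",
    "Liver",
    "Pancreas",
    "Kidney",
    "Colon",
    "Bladder",
    "Gonads",
    "Rectum",
    "Femoral head",
    "Skin",
    "Bone marrow",
    "Bone surface",
)

_CANONICAL_LOOKUP = {name.lower(): name for name in CANONICAL_ORGANS}


def canonical_name(name: str) -> str:
    """Return the canonical spelling of an organ name.

    Unknown names are returned trimmed but otherwise unchanged, so the
    pipeline also works with synthetic organ tables.
    """
    key = name.strip().lower()
    return _CANONICAL_LOOKUP.get(key, name.strip())


def organ_key(name: str) -> str:
    """Case-insensitive dictionary key for an organ name."""
    return name.strip().lower()


def round_half_even(value: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals with banker's (half-even) rounding.

    Goes through :class:`decimal.Decimal` on the shortest repr so that
    e.g. 0.645 (stored as 0.64499999...) rounds to 0.64 as its printed
    form demands, independent of binary representation noise.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_EVEN))


# --- domain types -----------------------------------------------------------


@dataclass(frozen=True)
class MeasurementPoint:
    """One rem-meter reading at the patient table.

    Parameters
    ----------
    distance_cm
        Horizontal distance from the isocenter, cm.
    h10_per_gray
        Neutron ambient dose equivalent H*(10) per Gy of photon dose
        delivered to the isocenter, mSv/Gy.
    sd_per_gray
        One-standard-deviation uncertainty of ``h10_per_gray``, mSv/Gy.
    """

    distance_cm: float
    h10_per_gray: float
    sd_per_gray: float = 0.0

    def __post_init__(self) -> None:
        if self.distance_cm < 0:
            raise ValidationError(f"distance_cm must be >= 0, got {self.distance_cm}")
        if not self.h10_per_gray > 0:
            raise ValidationError(
                f"h10_per_gray must be > 0, got {self.h10_per_gray} "
                f"at distance {self.distance_cm} cm"
            )
        if self.sd_per_gray < 0:
            raise ValidationError(f"sd_per_gray must be >= 0, got {self.sd_per_gray}")


@dataclass(frozen=True)
class MeasurementSet:
    """An ordered H*(10)-vs-distance measurement campaign.

    All values are normalized per Gy of photon dose at the isocenter.
    """

    points: tuple[MeasurementPoint, ...]
    normalization_note: str = "H*(10) per Gy of photon dose delivered to the isocenter"

    def __post_init__(self) -> None:
        pts = tuple(self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 2:
            raise ValidationError(
                f"a measurement set needs at least two points, got {len(pts)}"
            )
        dist = [p.distance_cm for p in pts]
        if not all(a < b for a, b in zip(dist, dist[1:])):
            raise ValidationError(f"distances must be strictly increasing, got {dist}")

    @property
    def distances_cm(self) -> tuple[float, ...]:
        return tuple(p.distance_cm for p in self.points)

    def point_at(self, distance_cm: float, *, atol: float = 1e-9) -> MeasurementPoint:
        """Return the point measured at ``distance_cm`` exactly."""
        for p in self.points:
            if abs(p.distance_cm - distance_cm) <= atol:
                return p
        raise ValidationError(
            f"no measurement at distance {distance_cm} cm "
            f"(available: {list(self.distances_cm)})"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_cm": [p.distance_cm for p in self.points],
                "h10_per_gray": [p.h10_per_gray for p in self.points],
                "sd_per_gray": [p.sd_per_gray for p in self.points],
            }
        )


@dataclass(frozen=True)
class DepthDoseCurve:
    """Tabulated neutron absorbed dose density vs depth in tissue.

    Only ratios of this curve enter the pipeline (depth correction
    factors), so its absolute scale and units (pGy·cm²) cancel.
    ``reference_depth_cm`` is the depth at which H*(10) is defined
    (10 mm in the ICRU sphere, hence the 1 cm default).
    """

    depths_cm: np.ndarray
    dose_density: np.ndarray
    reference_depth_cm: float = 1.0

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths_cm, dtype=float)
        dens = np.asarray(self.dose_density, dtype=float)
        object.__setattr__(self, "depths_cm", depths)
        object.__setattr__(self, "dose_density", dens)
        if depths.ndim != 1 or depths.size < 2:
            raise ValidationError("depth-dose curve needs at least two depth rows")
        if depths.shape != dens.shape:
            raise ValidationError("depths_cm and dose_density must have equal length")
        if not np.all(np.diff(depths) > 0):
            raise ValidationError(
                f"depths must be strictly increasing, got {depths.tolist()}"
            )
        if not np.all(dens > 0):
            bad = depths[dens <= 0].tolist()
            raise ValidationError(f"dose_density must be > 0 everywhere; bad depths {bad}")
        if not (depths[0] <= self.reference_depth_cm <= depths[-1]):
            raise ValidationError(
                f"reference_depth_cm {self.reference_depth_cm} outside the "
                f"tabulated range [{depths[0]}, {depths[-1]}]"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth_cm": self.depths_cm, "dose_density": self.dose_density}
        )


@dataclass(frozen=True)
class OrganGeometry:
    """Position of an organ's center relative to the beam.

    ``distance_cm`` is the horizontal distance from the beam central
    axis; ``depth_cm`` the depth below the body surface.
    """

    organ_name: str
    distance_cm: float
    depth_cm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "organ_name", canonical_name(self.organ_name))
        if self.distance_cm < 0:
            raise ValidationError(
                f"{self.organ_name}: distance_cm must be >= 0, got {self.distance_cm}"
            )
        if self.depth_cm < 0:
            raise ValidationError(
                f"{self.organ_name}: depth_cm must be >= 0, got {self.depth_cm}"
            )


@dataclass(frozen=True)
class DoseCoefficients:
    """NCRP-116 weighting factors and risk coefficients.

    ``tissue_weights`` / ``risk_coefficients`` map named organs to their
    W_T and fatal-cancer risk coefficient (in units of 10⁻² Sv⁻¹).
    Organs without an individual W_T form a single remainder compartment
    with weight ``remainder_weight`` and risk coefficient
    ``remainder_risk_coefficient``.  ``remainder_organs``, when given,
    closes the organ universe: an organ in neither table is an error at
    partition time.  ``marrow_distribution`` holds the active red
    bone-marrow fraction per skeletal region.
    """

    tissue_weights: Mapping[str, float]
    risk_coefficients: Mapping[str, float]
    genetic_coefficient: float = 1.00
    remainder_weight: float = 0.05
    remainder_risk_coefficient: float = 0.05
    marrow_distribution: Mapping[str, float] = field(default_factory=dict)
    remainder_organs: frozenset[str] | None = None

    def __post_init__(self) -> None:
        tw = {organ_key(k): float(v) for k, v in self.tissue_weights.items()}
        rc = {organ_key(k): float(v) for k, v in self.risk_coefficients.items()}
        md = {str(k).strip().lower(): float(v) for k, v in self.marrow_distribution.items()}
        object.__setattr__(self, "tissue_weights", tw)
        object.__setattr__(self, "risk_coefficients", rc)
        object.__setattr__(self, "marrow_distribution", md)
        if self.remainder_organs is not None:
            object.__setattr__(
                self,
                "remainder_organs",
                frozenset(organ_key(o) for o in self.remainder_organs),
            )
        for label, mapping in (("tissue_weights", tw), ("risk_coefficients", rc)):
            bad = {k: v for k, v in mapping.items() if v < 0}
            if bad:
                raise ValidationError(f"{label} must be >= 0; offending entries {bad}")
        missing = set(tw) - set(rc)
        if missing:
            raise ValidationError(
                f"named organs without a risk coefficient: {sorted(missing)}"
            )
        for scalar in ("genetic_coefficient", "remainder_weight", "remainder_risk_coefficient"):
            if getattr(self, scalar) < 0:
                raise ValidationError(f"{scalar} must be >= 0")
        bad_frac = {k: v for k, v in md.items() if not 0.0 <= v <= 1.0}
        if bad_frac:
            raise ValidationError(
                f"marrow_distribution fractions must lie in [0, 1]: {bad_frac}"
            )

    def is_named(self, organ: str) -> bool:
        return organ_key(organ) in self.tissue_weights


@dataclass(frozen=True)
class TreatmentPrescription:
    """Photon dose prescription of the treatment course."""

    prescribed_dose_gray: float
    dose_per_fraction_gray: float | None = None

    def __post_init__(self) -> None:
        if not self.prescribed_dose_gray > 0:
            raise ValidationError("prescribed_dose_gray must be > 0")
        if self.dose_per_fraction_gray is not None:
            if not self.dose_per_fraction_gray > 0:
                raise ValidationError("dose_per_fraction_gray must be > 0")
            n = self.prescribed_dose_gray / self.dose_per_fraction_gray
            if abs(n - round(n)) > 1e-9:
                raise ValidationError(
                    f"prescribed dose {self.prescribed_dose_gray} Gy is not an "
                    f"integer number of {self.dose_per_fraction_gray}-Gy fractions"
                )

    @property
    def n_fractions(self) -> int | None:
        if self.dose_per_fraction_gray is None:
            return None
        return round(self.prescribed_dose_gray / self.dose_per_fraction_gray)


# --- CSV I/O ----------------------------------------------------------------


def _read_table(source, required: Iterable[str]) -> pd.DataFrame:
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: file is empty") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path}: no data rows")
    return df


def load_measurement_set(source) -> MeasurementSet:
    """Read a distance / H*(10) / sd CSV into a validated MeasurementSet.

    The set is sorted by distance before validation; values must be per
    Gy at the isocenter.
    """
    df = _read_table(source, ["distance_cm", "h10_per_gray", "sd_per_gray"])
    df = df.sort_values("distance_cm", kind="stable")
    points = []
    for i, row in df.iterrows():
        try:
            points.append(
                MeasurementPoint(
                    float(row["distance_cm"]),
                    float(row["h10_per_gray"]),
                    float(row["sd_per_gray"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{source}, row {i}: {exc}") from exc
    return MeasurementSet(tuple(points))


def write_measurement_set(ms: MeasurementSet, dest) -> None:
    ms.to_frame().to_csv(dest, index=False)


def load_depth_dose_curve(source, reference_depth_cm: float = 1.0) -> DepthDoseCurve:
    df = _read_table(source, ["depth_cm", "dose_density"])
    return DepthDoseCurve(
        df["depth_cm"].to_numpy(float),
        df["dose_density"].to_numpy(float),
        reference_depth_cm=reference_depth_cm,
    )


def write_depth_dose_curve(curve: DepthDoseCurve, dest) -> None:
    curve.to_frame().to_csv(dest, index=False)


def load_organ_geometry(source) -> dict[str, OrganGeometry]:
    """Read the organ geometry CSV, keyed by unique (case-folded) organ name."""
    df = _read_table(source, ["organ_name", "distance_cm", "depth_cm"])
    organs: dict[str, OrganGeometry] = {}
    for i, row in df.iterrows():
        geo = OrganGeometry(
            str(row["organ_name"]), float(row["distance_cm"]), float(row["depth_cm"])
        )
        key = organ_key(geo.organ_name)
        if key in organs:
            raise ValidationError(f"{source}, row {i}: duplicate organ {geo.organ_name!r}")
        organs[key] = geo
    return organs


def write_organ_geometry(organs: Mapping[str, OrganGeometry], dest) -> None:
    pd.DataFrame(
        {
            "organ_name": [g.organ_name for g in organs.values()],
            "distance_cm": [g.distance_cm for g in organs.values()],
            "depth_cm": [g.depth_cm for g in organs.values()],
        }
    ).to_csv(dest, index=False)


def load_marrow_distribution(source) -> dict[str, float]:
    df = _read_table(source, ["region", "fraction"])
    return {
        str(r["region"]).strip().lower(): float(r["fraction"]) for _, r in df.iterrows()
    }


def load_coefficients(source, marrow_source=None) -> DoseCoefficients:
    """Read the coefficient CSV (named rows, remainder rows, scalar rows).

    Rows with compartment ``named`` carry W_T and a risk coefficient;
    ``remainder`` rows only declare compartment membership; the two
    ``scalar`` rows carry the remainder-compartment weight/coefficient
    and the genetic-effects coefficient.
    """
    df = _read_table(source, ["organ_name", "compartment", "w_t", "risk_coefficient_1e2_per_sv"])
    tw: dict[str, float] = {}
    rc: dict[str, float] = {}
    remainder: set[str] = set()
    remainder_weight = 0.05
    remainder_risk = 0.05
    genetic = 1.00
    for i, row in df.iterrows():
        name = str(row["organ_name"]).strip()
        kind = str(row["compartment"]).strip().lower()
        if kind == "named":
            tw[name] = float(row["w_t"])
            rc[name] = float(row["risk_coefficient_1e2_per_sv"])
        elif kind == "remainder":
            remainder.add(name)
        elif kind == "scalar":
            if "remainder" in name.lower():
                remainder_weight = float(row["w_t"])
                remainder_risk = float(row["risk_coefficient_1e2_per_sv"])
            elif "genetic" in name.lower():
                genetic = float(row["risk_coefficient_1e2_per_sv"])
            else:
                raise ValidationError(f"{source}, row {i}: unknown scalar row {name!r}")
        else:
            raise ValidationError(f"{source}, row {i}: unknown compartment {kind!r}")
    marrow = load_marrow_distribution(marrow_source) if marrow_source else {}
    return DoseCoefficients(
        tissue_weights=tw,
        risk_coefficients=rc,
        genetic_coefficient=genetic,
        remainder_weight=remainder_weight,
        remainder_risk_coefficient=remainder_risk,
        marrow_distribution=marrow,
        remainder_organs=frozenset(remainder) if remainder else None,
    )


def load_organ_dose_override(source) -> dict[str, tuple[float, float]]:
    """Read an organ-dose override CSV: organ -> (total mSv, sd mSv)."""
    df = _read_table(source, ["organ_name", "total_mSv", "sd_mSv"])
    out: dict[str, tuple[float, float]] = {}
    for i, row in df.iterrows():
        total = float(row["total_mSv"])
        sd = float(row["sd_mSv"])
        if total < 0 or sd < 0:
            raise ValidationError(f"{source}, row {i}: negative dose or sd")
        out[organ_key(str(row["organ_name"]))] = (total, sd)
    return out


# --- bundled fixtures -------------------------------------------------------


def data_path(filename: str) -> Path:
    """Path to a bundled reference data file."""
    return Path(resources.files("neudose").joinpath("data", filename))


def paper_fixtures() -> tuple[
    MeasurementSet,
    DepthDoseCurve,
    dict[str, OrganGeometry],
    DoseCoefficients,
    TreatmentPrescription,
]:
    """In-memory copies of the bundled printed reference tables.

    Returns the rem-meter measurement set (1.30/0.71/0.58 mSv/Gy at
    0/20/60 cm), the 0.5-MeV neutron depth-dose curve (11 rows, 1-16 cm),
    the 18-organ geometry table, the NCRP-116 coefficient set with the
    red-marrow skeletal distribution, and the 60 Gy / 2 Gy-per-fraction
    prescription.
    """
    measurements = load_measurement_set(data_path("measurements.csv"))
    curve = load_depth_dose_curve(data_path("depth_dose.csv"))
    organs = load_organ_geometry(data_path("organ_geometry.csv"))
    coefficients = load_coefficients(
        data_path("coefficients.csv"), data_path("marrow_distribution.csv")
    )
    prescription = TreatmentPrescription(60.0, 2.0)
    return measurements, curve, organs, coefficients, prescription
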