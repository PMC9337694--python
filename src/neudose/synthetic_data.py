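"""Synthetic measurement campaigns with known ground truth.

The generators emulate the structure of a patient-table neutron survey
without any neutron physics:

* the distance profile of H*(10) is exponential-plus-floor,
  ``truth(d) = floor + (h0 - floor)·exp(-d / decay_length)``, which
  reproduces the observed "rapid then smooth" fall-off with two
  interpretable parameters;
* measurement noise is Normal with a fixed coefficient of variation,
  truncated at zero (the survey protocol reports the mean ± sd of three
  repeats but no distribution; Normal is the minimal assumption);
* the synthetic depth-dose curve is a pure exponential, for which the
  log-linear interpolant is exact — handy for testing the depth
  correction in closed form.

Everything is driven by :func:`numpy.random.default_rng` seeds and is
bit-reproducible.  :func:`oracle_pipeline` re-implements the entire
dose/risk arithmetic by direct scalar computation, sharing no code with
the production modules, and serves as the equivalence oracle in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Literal, Mapping

import numpy as np

from .reference_data import (
    DepthDoseCurve,
    DoseCoefficients,
    MeasurementPoint,
    MeasurementSet,
    OrganGeometry,
    TreatmentPrescription,
    ValidationError,
)

__all__ = [
    "CampaignSpec",
    "SyntheticTruth",
    "generate_campaign",
    "generate_depth_dose_curve",
    "generate_organ_table",
    "oracle_pipeline",
]


@dataclass(frozen=True)
class CampaignSpec:
    """Parameters of a synthetic H*(10) survey.

    Defaults emulate the reference campaign: 1.30 mSv/Gy at the
    isocenter decaying toward a ~0.55 mSv/Gy room-scatter floor with an
    11-cm decay length (within 10% of the measured 1.30/0.71/0.58
    profile at 0/20/60 cm), three repeats per point with 5% relative
    noise.
    """

    h0: float = 1.30
    decay_length_cm: float = 11.0
    floor: float = 0.55
    noise_cv: float = 0.05
    distances_cm: tuple[float, ...] = (0.0, 20.0, 60.0)
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.h0 > self.floor >= 0:
            raise ValidationError("need h0 > floor >= 0")
        if self.decay_length_cm <= 0:
            raise ValidationError("decay_length_cm must be > 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if len(self.distances_cm) < 2:
            raise ValidationError("need at least two sampling distances")

    def truth(self, distance_cm: float) -> float:
        """Noiseless profile value at ``distance_cm``."""
        return self.floor + (self.h0 - self.floor) * math.exp(
            -distance_cm / self.decay_length_cm
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth accompanying a generated campaign."""

    spec: CampaignSpec
    true_profile: Mapping[float, float]
    true_curve: DepthDoseCurve | None = None
    true_organ_doses: Mapping[str, float] = field(default_factory=dict)


def generate_campaign(spec: CampaignSpec) -> tuple[MeasurementSet, SyntheticTruth]:
    """Simulate a survey: per distance, average ``replicates`` noisy draws.

    Each reading is Normal(truth, noise_cv·truth) truncated at zero (a
    rem-meter cannot read negative); the point's value is the replicate
    mean and its sd the population standard deviation of the replicates
    (ddof=0; see the methods note for the resulting ±1 sd coverage).
    """
    rng = np.random.default_rng(spec.seed)
    points = []
    profile = {}
    for d in sorted(spec.distances_cm):
        mu = spec.truth(d)
        profile[d] = mu
        if spec.noise_cv == 0.0:
            mean, sd = mu, 0.0
        else:
            draws = rng.normal(mu, spec.noise_cv * mu, size=spec.replicates)
            draws = np.clip(draws, 0.0, None)
            mean = float(np.mean(draws))
            sd = float(np.std(draws, ddof=0)) if spec.replicates > 1 else 0.0
        points.append(MeasurementPoint(d, mean, sd))
    truth = SyntheticTruth(spec=spec, true_profile=profile)
    return MeasurementSet(tuple(points)), truth


def with_organ_truth(
    truth: SyntheticTruth,
    curve: DepthDoseCurve,
    organs: Mapping[str, OrganGeometry],
    prescription: TreatmentPrescription,
    scheme: Literal["linear", "log-linear"] = "linear",
) -> SyntheticTruth:
    """Fill ``true_organ_doses`` by running the oracle on the noiseless profile."""
    noiseless = MeasurementSet(
        tuple(
            MeasurementPoint(d, truth.true_profile[d], 0.0)
            for d in sorted(truth.true_profile)
        )
    )
    result = oracle_pipeline(
        noiseless, curve, organs, _NULL_COEFFICIENTS, prescription, scheme, "precise"
    )
    return SyntheticTruth(
        spec=truth.spec,
        true_profile=truth.true_profile,
        true_curve=curve,
        true_organ_doses=result["totals"],
    )


def generate_depth_dose_curve(
    mu_per_cm: float,
    amplitude: float = 18.39 * math.exp(0.3207),
    depths_cm: tuple[float, ...] | np.ndarray = tuple(range(1, 17)),
    reference_depth_cm: float = 1.0,
) -> DepthDoseCurve:
    """Exponentially attenuating depth-dose curve, dose = A·exp(-mu·z).

    The default attenuation coefficient mu ≈ 0.3207 cm⁻¹ solves
    value(16)/value(1) = 0.15/18.39 (the span of the tabulated 0.5-MeV
    curve), with the amplitude fixed so value(1 cm) = 18.39.
    """
    if mu_per_cm <= 0:
        raise ValidationError("mu_per_cm must be > 0")
    z = np.asarray(depths_cm, dtype=float)
    return DepthDoseCurve(z, amplitude * np.exp(-mu_per_cm * z), reference_depth_cm)


def generate_organ_table(
    n_organs: int,
    distance_range_cm: tuple[float, float] = (5.0, 83.88),
    depth_range_cm: tuple[float, float] = (1.0, 16.0),
    seed: int = 0,
) -> dict[str, OrganGeometry]:
    """Uniformly sampled synthetic organ geometries with unique names.

    Default ranges span the extremes of the reference organ table, so
    every generated organ is admissible under the default bin rule and
    depth-dose grid.
    """
    if n_organs < 1:
        raise ValidationError("n_organs must be >= 1")
    lo_d, hi_d = distance_range_cm
    lo_z, hi_z = depth_range_cm
    if not (0 <= lo_d <= hi_d and 0 <= lo_z <= hi_z):
        raise ValidationError("invalid distance or depth range")
    rng = np.random.default_rng(seed)
    organs: dict[str, OrganGeometry] = {}
    for i in range(n_organs):
        name = f"synthetic organ {i:03d}"
        organs[name] = OrganGeometry(
            name,
            float(rng.uniform(lo_d, hi_d)),
            float(rng.uniform(lo_z, hi_z)),
        )
    return organs


# --- independent brute-force oracle ----------------------------------------
#
# Everything below re-derives the pipeline outputs with plain scalar
# arithmetic (math + decimal, no numpy vectorization, no imports from the
# dosimetry/composite/risk modules) so tests can assert dual-route
# equality.  Keep it boring and literal.

#: Minimal coefficient set: no named organs, everything remainder.
_NULL_COEFFICIENTS = DoseCoefficients(tissue_weights={}, risk_coefficients={})

_ORACLE_REGIONS = {
    "head": ("brain", 0.131),
    "upper limb-girdle": ("breast", 0.062),
    "sternum": ("heart", 0.034),
    "ribs": ("heart", 0.141),
    "vertebrae": ("cord", 0.109),
    "sacrum": ("femoral head", 0.139),
    "lower girdle": ("femoral head", 0.261),
}


def _oracle_round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def _oracle_interp(depths, values, z, scheme):
    if z <= depths[0]:
        return values[0]
    if z >= depths[-1]:
        return values[-1]
    for i in range(len(depths) - 1):
        if depths[i] <= z <= depths[i + 1]:
            t = (z - depths[i]) / (depths[i + 1] - depths[i])
            if scheme == "linear":
                return values[i] + t * (values[i + 1] - values[i])
            return values[i] * (values[i + 1] / values[i]) ** t
    raise AssertionError("unreachable")


def oracle_pipeline(
    measurements: MeasurementSet,
    curve: DepthDoseCurve,
    organs: Mapping[str, OrganGeometry],
    coefficients: DoseCoefficients,
    prescription: TreatmentPrescription,
    scheme: Literal["linear", "log-linear"] = "linear",
    rounding_mode: Literal["paper", "precise"] = "precise",
    marrow_normalization: Literal["as-printed", "renormalized"] = "as-printed",
    overrides: Mapping[str, tuple[float, float]] | None = None,
) -> dict:
    """Brute-force recomputation of every pipeline output.

    Assumes the default bin rule ([5, 40] → 20 cm, (40, 80] → 60 cm,
    clamp beyond) and the default skeletal region map.  Returns a dict
    with per-organ totals (mSv), per-Gy doses, effective dose, risks and
    genetic effects, computed by direct scalar arithmetic.
    """
    depths = [float(z) for z in curve.depths_cm]
    dens = [float(v) for v in curve.dose_density]
    ref = _oracle_interp(depths, dens, curve.reference_depth_cm, scheme)
    h = {p.distance_cm: p.h10_per_gray for p in measurements.points}
    course = prescription.prescribed_dose_gray

    per_gray: dict[str, float] = {}
    totals: dict[str, float] = {}
    for key, geo in organs.items():
        key = key.strip().lower()
        if geo.distance_cm < 5.0:
            raise ValidationError(f"oracle: {key} inside the field margin")
        h10 = h[20.0] if geo.distance_cm <= 40.0 else h[60.0]
        pg = h10 * _oracle_interp(depths, dens, geo.depth_cm, scheme) / ref
        if rounding_mode == "paper":
            pg = _oracle_round2(pg)
        per_gray[key] = pg
        totals[key] = pg * course

    # skin: plain average of the two bin points, never rounded per-Gy
    per_gray["skin"] = (h[20.0] + h[60.0]) / 2.0
    totals["skin"] = per_gray["skin"] * course

    # red marrow / bone surface via surrogate skeletal regions (skipped when
    # the organ table lacks the surrogates, e.g. purely synthetic tables)
    surrogates_present = all(
        s in totals for (s, _w) in _ORACLE_REGIONS.values()
    )
    if surrogates_present:
        wsum = sum(w for (_, w) in _ORACLE_REGIONS.values())
        marrow = 0.0
        for region, (surrogate, w) in _ORACLE_REGIONS.items():
            if marrow_normalization == "renormalized":
                w = w / wsum
            marrow += w * totals[surrogate]
        totals["bone marrow"] = marrow
        per_gray["bone marrow"] = marrow / course
        bs_regions = [r for r in _ORACLE_REGIONS if r != "head"]
        bone_surface = sum(totals[_ORACLE_REGIONS[r][0]] for r in bs_regions) / len(bs_regions)
        totals["bone surface"] = bone_surface
        per_gray["bone surface"] = bone_surface / course

    if overrides:
        for name, (total, _sd) in overrides.items():
            name = name.strip().lower()
            totals[name] = total
            per_gray[name] = total / course

    named = {k: v for k, v in totals.items() if k in coefficients.tissue_weights}
    rest = [v for k, v in totals.items() if k not in coefficients.tissue_weights]

    eff = sum(coefficients.tissue_weights[k] * v for k, v in named.items())
    if rest:
        eff += coefficients.remainder_weight * (sum(rest) / len(rest))

    risks = {
        k: v / 1000.0 * coefficients.risk_coefficients[k] * 1e-2 * 1e6
        for k, v in named.items()
    }
    if rest:
        risks["remainder"] = (
            sum(rest) / 1000.0 * coefficients.remainder_risk_coefficient * 1e-2 * 1e6
        )
    genetic = None
    if "gonads" in totals:
        genetic = totals["gonads"] / 1000.0 * coefficients.genetic_coefficient * 1e-2 * 1e6

    return {
        "per_gray": per_gray,
        "totals": totals,
        "effective_dose_mSv": eff,
        "per_organ_risk": risks,
        "total_risk": sum(risks.values()),
        "genetic_effects": genetic,
    }
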