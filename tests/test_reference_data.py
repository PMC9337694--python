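"""Reference tables: loading, validation, bundled fixture fidelity."""

import numpy as np
import pytest

from neudose import (
    DepthDoseCurve,
    MeasurementPoint,
    MeasurementSet,
    SchemaError,
    TreatmentPrescription,
    ValidationError,
    load_depth_dose_curve,
    load_measurement_set,
    load_organ_geometry,
)
from neudose.reference_data import (
    canonical_name,
    round_half_even,
    write_depth_dose_curve,
    write_measurement_set,
    write_organ_geometry,
)


def _write(path, text):
    path.write_text(text)
    return path


class TestMeasurementSet:
    def test_loads_campaign_csv(self, tmp_path):
        p = _write(
            tmp_path / "m.csv",
            "distance_cm,h10_per_gray,sd_per_gray\n0,1.30,0.14\n20,0.71,0.12\n60,0.58,0.10\n",
        )
        ms = load_measurement_set(p)
        assert len(ms.points) == 3
        assert ms.point_at(20.0).h10_per_gray == 0.71
        assert ms.point_at(60.0).sd_per_gray == 0.10

    def test_single_row_rejected(self, tmp_path):
        p = _write(tmp_path / "m.csv", "distance_cm,h10_per_gray,sd_per_gray\n0,1.3,0.1\n")
        with pytest.raises(ValidationError, match="two points"):
            load_measurement_set(p)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = _write(tmp_path / "m.csv", "distance_cm,h10_per_gray\n0,1.3\n20,0.7\n")
        with pytest.raises(SchemaError, match="sd_per_gray"):
            load_measurement_set(p)

    def test_nonpositive_h10_names_the_row(self, tmp_path):
        p = _write(
            tmp_path / "m.csv",
            "distance_cm,h10_per_gray,sd_per_gray\n0,1.3,0.1\n20,-0.7,0.1\n",
        )
        with pytest.raises(ValidationError, match="row 1"):
            load_measurement_set(p)

    def test_round_trip_identity(self, tmp_path, measurements):
        out = tmp_path / "rt.csv"
        write_measurement_set(measurements, out)
        again = load_measurement_set(out)
        assert again == measurements

    def test_duplicate_distance_rejected(self):
        pts = (MeasurementPoint(20, 0.7, 0.1), MeasurementPoint(20, 0.7, 0.1))
        with pytest.raises(ValidationError, match="strictly increasing"):
            MeasurementSet(pts)


class TestDepthDoseCurve:
    def test_bundled_curve_spans_printed_rows(self, curve):
        assert curve.depths_cm[0] == 1.0 and curve.depths_cm[-1] == 16.0
        assert curve.dose_density[0] == 18.39 and curve.dose_density[-1] == 0.15
        assert len(curve.depths_cm) == 11

    def test_duplicated_depth_rejected(self, tmp_path):
        p = _write(tmp_path / "c.csv", "depth_cm,dose_density\n1,18.39\n1,16.11\n")
        with pytest.raises(ValidationError, match="strictly increasing"):
            load_depth_dose_curve(p)

    def test_reference_depth_outside_grid_rejected(self):
        with pytest.raises(ValidationError, match="reference_depth"):
            DepthDoseCurve(np.array([1.0, 2.0]), np.array([2.0, 1.0]), reference_depth_cm=5.0)

    def test_nonpositive_density_rejected(self, tmp_path):
        p = _write(tmp_path / "c.csv", "depth_cm,dose_density\n1,18.39\n2,0\n")
        with pytest.raises(ValidationError, match="> 0"):
            load_depth_dose_curve(p)

    def test_round_trip_identity(self, tmp_path, curve):
        out = tmp_path / "rt.csv"
        write_depth_dose_curve(curve, out)
        again = load_depth_dose_curve(out)
        assert np.array_equal(again.depths_cm, curve.depths_cm)
        assert np.array_equal(again.dose_density, curve.dose_density)


class TestOrganGeometry:
    def test_bundled_table_has_18_organs(self, organs):
        assert len(organs) == 18
        assert organs["thyroid"].distance_cm == 15.28
        assert organs["thyroid"].depth_cm == 2.0
        assert organs["gonads"].distance_cm == 79.88
        assert organs["gonads"].depth_cm == 1.0

    def test_empty_file_rejected(self, tmp_path):
        p = _write(tmp_path / "o.csv", "organ_name,distance_cm,depth_cm\n")
        with pytest.raises(ValidationError):
            load_organ_geometry(p)

    def test_duplicate_organ_rejected(self, tmp_path):
        p = _write(
            tmp_path / "o.csv",
            "organ_name,distance_cm,depth_cm\nLiver,44,8\nliver ,44,8\n",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            load_organ_geometry(p)

    def test_round_trip_identity(self, tmp_path, organs):
        out = tmp_path / "rt.csv"
        write_organ_geometry(organs, out)
        assert load_organ_geometry(out) == organs


class TestCoefficients:
    def test_breast_row_matches_reference(self, coefficients):
        assert coefficients.tissue_weights["breast"] == 0.05
        assert coefficients.risk_coefficients["breast"] == 0.20

    def test_full_named_table(self, coefficients):
        expected_w = {
            "bladder": 0.05, "bone marrow": 0.12, "bone surface": 0.01,
            "breast": 0.05, "esophagus": 0.05, "colon": 0.12, "liver": 0.05,
            "lung": 0.12, "gonads": 0.20, "skin": 0.01, "stomach": 0.12,
            "thyroid": 0.05,
        }
        assert coefficients.tissue_weights == expected_w
        expected_r = {
            "bladder": 0.30, "bone marrow": 0.50, "bone surface": 0.05,
            "breast": 0.20, "esophagus": 0.30, "colon": 0.85, "liver": 0.15,
            "lung": 0.85, "gonads": 0.10, "skin": 0.02, "stomach": 1.10,
            "thyroid": 0.08,
        }
        assert coefficients.risk_coefficients == expected_r
        assert coefficients.remainder_weight == 0.05
        assert coefficients.remainder_risk_coefficient == 0.05
        assert coefficients.genetic_coefficient == 1.00

    def test_marrow_distribution_sums_to_0877(self, coefficients):
        md = coefficients.marrow_distribution
        assert md == {
            "head": 0.131, "upper limb-girdle": 0.062, "sternum": 0.034,
            "ribs": 0.141, "vertebrae": 0.109, "sacrum": 0.139,
            "lower girdle": 0.261,
        }
        assert sum(md.values()) == pytest.approx(0.877, abs=1e-12)


class TestPrescription:
    def test_fixture_is_60_gray_in_2_gray_fractions(self, prescription):
        assert prescription.prescribed_dose_gray == 60.0
        assert prescription.dose_per_fraction_gray == 2.0
        assert prescription.n_fractions == 30

    def test_non_integer_fractionation_rejected(self):
        with pytest.raises(ValidationError, match="fraction"):
            TreatmentPrescription(60.0, 1.7)


@pytest.mark.parametrize(
    "raw,canonical",
    [(" thyroid ", "Thyroid"), ("FEMORAL HEAD", "Femoral head"),
     ("Salivary Glands", "Salivary glands"), ("mystery organ", "mystery organ")],
)
def test_canonical_name(raw, canonical):
    assert canonical_name(raw) == canonical


@pytest.mark.parametrize(
    "value,expected",
    [(0.645, 0.64), (0.655, 0.66), (0.62197, 0.62), (0.005, 0.0), (0.015, 0.02)],
)
def test_round_half_even(value, expected):
    assert round_half_even(value, 2) == expected
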