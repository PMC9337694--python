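"""Distance-bin assignment, depth correction and per-organ doses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neudose import (
    DEFAULT_BIN_RULE,
    DistanceBin,
    DistanceBinRule,
    ValidationError,
    assign_distance_bin,
    classify_depth,
    depth_class_means,
    depth_correction_factor,
    interpolate_depth_dose,
    organ_equivalent_dose,
    organ_equivalent_doses,
)
from neudose.reference_data import OrganGeometry


class TestInterpolation:
    @pytest.mark.parametrize("scheme", ["linear", "log-linear"])
    @pytest.mark.parametrize("depth,expected", [(1.0, 18.39), (2.0, 16.11), (16.0, 0.15)])
    def test_exact_at_grid_points(self, curve, scheme, depth, expected):
        assert interpolate_depth_dose(curve, depth, scheme) == pytest.approx(expected)

    def test_linear_between_points(self, curve):
        # hand interpolation between (8, 2.79) and (10, 1.40)
        assert interpolate_depth_dose(curve, 9.5, "linear") == pytest.approx(1.7475)

    def test_log_linear_between_points(self, curve):
        expected = 2.79 * (1.40 / 2.79) ** 0.75
        assert interpolate_depth_dose(curve, 9.5, "log-linear") == pytest.approx(expected)

    def test_no_extrapolation_toward_surface(self, curve):
        with pytest.raises(ValidationError, match="above the tabulated range"):
            interpolate_depth_dose(curve, 0.5)

    def test_beyond_grid_clamps_with_warning(self, curve):
        with pytest.warns(UserWarning, match="clamping"):
            value = interpolate_depth_dose(curve, 25.0)
        assert value == pytest.approx(0.15)

    @pytest.mark.parametrize("scheme", ["linear", "log-linear"])
    def test_bounded_by_bracketing_grid_values(self, curve, scheme):
        rng = np.random.default_rng(42)
        for depth in rng.uniform(1.0, 16.0, size=200):
            value = interpolate_depth_dose(curve, float(depth), scheme)
            i = np.searchsorted(curve.depths_cm, depth, side="right") - 1
            i = min(i, len(curve.depths_cm) - 2)
            lo = min(curve.dose_density[i], curve.dose_density[i + 1])
            hi = max(curve.dose_density[i], curve.dose_density[i + 1])
            assert lo - 1e-12 <= value <= hi + 1e-12


class TestDepthCorrectionFactor:
    def test_unity_at_reference_depth(self, curve):
        assert depth_correction_factor(curve, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "depth,expected", [(2.0, 16.11 / 18.39), (16.0, 0.15 / 18.39)]
    )
    def test_ratio_of_tabulated_rows(self, curve, depth, expected):
        assert depth_correction_factor(curve, depth) == pytest.approx(expected)

    @pytest.mark.parametrize("scheme", ["linear", "log-linear"])
    def test_at_most_one_and_decreasing(self, curve, scheme):
        depths = np.linspace(1.0, 16.0, 601)
        factors = [depth_correction_factor(curve, float(z), scheme) for z in depths]
        assert all(f <= 1.0 + 1e-12 for f in factors)
        assert all(a >= b - 1e-12 for a, b in zip(factors, factors[1:]))
        on_grid = [depth_correction_factor(curve, float(z), scheme) for z in curve.depths_cm]
        assert all(a > b for a, b in zip(on_grid, on_grid[1:]))


class TestDistanceBins:
    def test_near_bin_uses_20cm_point(self, measurements):
        point = assign_distance_bin(DEFAULT_BIN_RULE, measurements, 15.28)
        assert point.h10_per_gray == 0.71

    def test_far_bin_uses_60cm_point(self, measurements):
        point = assign_distance_bin(DEFAULT_BIN_RULE, measurements, 79.88)
        assert point.h10_per_gray == 0.58

    def test_beyond_last_bin_clamps(self, measurements):
        point = assign_distance_bin(DEFAULT_BIN_RULE, measurements, 83.88)
        assert point.distance_cm == 60.0

    def test_beyond_last_bin_with_error_policy(self, measurements):
        rule = DistanceBinRule(DEFAULT_BIN_RULE.bins, out_of_range_policy="error")
        with pytest.raises(ValidationError, match="beyond the last bin"):
            assign_distance_bin(rule, measurements, 83.88)

    def test_in_field_distance_rejected(self, measurements):
        with pytest.raises(ValidationError, match="treatment-field"):
            assign_distance_bin(DEFAULT_BIN_RULE, measurements, 3.0)

    def test_bin_boundary_belongs_to_near_bin(self, measurements):
        assert assign_distance_bin(DEFAULT_BIN_RULE, measurements, 40.0).distance_cm == 20.0
        assert assign_distance_bin(DEFAULT_BIN_RULE, measurements, 40.01).distance_cm == 60.0

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            DistanceBinRule((DistanceBin(5, 40, 20), DistanceBin(30, 80, 60)))

    def test_rule_cross_checks_measurements(self, measurements):
        rule = DistanceBinRule((DistanceBin(5, 40, 25),))
        problems = rule.validate_against(measurements)
        assert len(problems) == 1 and "25" in problems[0]


class TestOrganEquivalentDose:
    def test_thyroid_paper_mode(self, paper):
        m, c, o, _, p = paper
        d = organ_equivalent_dose(o["thyroid"], m, c, prescription=p, rounding_mode="paper")
        assert d.per_gray == pytest.approx(0.62)
        assert d.total == pytest.approx(37.2)

    def test_gonads_paper_mode(self, paper):
        m, c, o, _, p = paper
        d = organ_equivalent_dose(o["gonads"], m, c, prescription=p, rounding_mode="paper")
        assert d.per_gray == pytest.approx(0.58)
        assert d.total == pytest.approx(34.8)

    def test_breast_precise_mode(self, paper):
        m, c, o, _, p = paper
        d = organ_equivalent_dose(o["breast"], m, c, prescription=p, rounding_mode="precise")
        assert d.per_gray == pytest.approx(0.71 * 16.11 / 18.39)
        assert d.total == pytest.approx(0.71 * 16.11 / 18.39 * 60)

    def test_reference_depth_organ_gets_bin_h10_exactly(self, paper):
        m, c, _, _, p = paper
        organ = OrganGeometry("near surface organ", 10.0, 1.0)
        d = organ_equivalent_dose(organ, m, c, prescription=p)
        assert d.per_gray == pytest.approx(0.71)
        assert d.depth_factor == pytest.approx(1.0)

    def test_monotone_non_increasing_in_depth(self, paper):
        m, c, _, _, p = paper
        doses = [
            organ_equivalent_dose(OrganGeometry(f"o{z}", 20.0, z), m, c, prescription=p).total
            for z in np.linspace(1.0, 16.0, 31)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(doses, doses[1:]))

    def test_monotone_non_increasing_across_bins(self, paper):
        m, c, _, _, p = paper
        doses = [
            organ_equivalent_dose(OrganGeometry(f"o{x}", x, 2.0), m, c, prescription=p).total
            for x in np.linspace(5.0, 83.0, 40)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(doses, doses[1:]))

    def test_rounding_bound_between_modes(self, paper):
        m, c, o, _, p = paper
        for geo in o.values():
            paper_d = organ_equivalent_dose(o[geo.organ_name.lower()], m, c,
                                            prescription=p, rounding_mode="paper")
            precise_d = organ_equivalent_dose(o[geo.organ_name.lower()], m, c,
                                              prescription=p, rounding_mode="precise")
            assert abs(paper_d.total - precise_d.total) <= 0.005 * p.prescribed_dose_gray


class TestDepthClasses:
    @pytest.mark.parametrize(
        "depth,expected",
        [(2.0, "surface"), (5.0, "surface"), (5.01, "middle"), (10.0, "middle"),
         (10.01, "deep"), (15.0, "deep"), (16.0, "unclassified")],
    )
    def test_half_open_intervals(self, depth, expected):
        assert classify_depth(depth) == expected

    def test_negative_depth_rejected(self):
        with pytest.raises(ValidationError):
            classify_depth(-1.0)

    def test_class_means_paper_mode(self, paper):
        m, c, o, _, p = paper
        doses = organ_equivalent_doses(o, m, c, prescription=p, rounding_mode="paper")
        means = depth_class_means(doses.values(), decimals=2)
        assert means["surface"] == pytest.approx(0.61)
        assert means["deep"] == pytest.approx(0.02)
        assert "unclassified" in means  # cord at 16 cm, reported separately

    def test_single_organ_class_is_identity(self, paper):
        m, c, _, _, p = paper
        d = organ_equivalent_dose(OrganGeometry("solo", 20.0, 2.0), m, c, prescription=p)
        means = depth_class_means([d])
        assert means == {"surface": pytest.approx(d.per_gray)}


@given(depth=st.floats(min_value=0.0, max_value=30.0, allow_nan=False))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_classify_depth_total_on_nonnegatives(depth):
    assert classify_depth(depth) in ("surface", "middle", "deep", "unclassified")
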