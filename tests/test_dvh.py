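import numpy as np
import pytest

import lorp
from lorp.dvh import (
    CriteriaSet,
    CriterionRow,
    classify_plan,
    cumulative_dvh,
    metric_d,
    metric_v,
)


@pytest.fixture(scope="module")
def random_field(small_grid):
    rng = np.random.default_rng(12)
    dose = lorp.DoseGrid(rng.uniform(0.0, 30.0, small_grid.shape), small_grid)
    mask = lorp.Structure("s", rng.random(small_grid.shape) > 0.6, small_grid)
    return dose, mask


@pytest.fixture
def uniform_25(small_grid):
    dose = lorp.DoseGrid(np.full(small_grid.shape, 25.0), small_grid)
    mask = np.zeros(small_grid.shape, bool)
    mask[4:20, 4:20, 4:20] = True
    return dose, lorp.Structure("s", mask, small_grid)


class TestCumulativeDvh:
    def test_uniform_dose_is_step_function(self, uniform_25):
        dose, mask = uniform_25
        curve = cumulative_dvh(dose, mask)
        assert curve.volume_at(0.0) == 1.0
        assert curve.volume_at(24.9) == 1.0
        assert curve.volume_at(26.0) == 0.0
        assert curve.volume_fraction[-1] == 0.0
        assert curve.total_volume_cm3 == pytest.approx(mask.volume_cm3)

    def test_monotone_nonincreasing(self, random_field):
        curve = cumulative_dvh(*random_field)
        assert (np.diff(curve.volume_fraction) <= 1e-12).all()

    def test_matches_sorting_oracle(self, random_field):
        dose, mask = random_field
        curve = cumulative_dvh(dose, mask, bin_width_gy=0.25)
        d = dose.values[mask.mask]
        for edge, frac in zip(curve.dose_bins_gy, curve.volume_fraction):
            assert frac == pytest.approx((d >= edge).mean())

    def test_empty_mask_rejected(self, small_grid):
        dose = lorp.DoseGrid(np.zeros(small_grid.shape), small_grid)
        empty = lorp.Structure("s", np.zeros(small_grid.shape, bool), small_grid)
        with pytest.raises(ValueError):
            cumulative_dvh(dose, empty)


class TestMetricV:
    def test_uniform_dose_full_coverage(self, uniform_25):
        assert metric_v(*uniform_25, dose_level_gy=25.0) == 100.0

    def test_half_and_half_absolute_volume(self, small_grid):
        values = np.zeros(small_grid.shape)
        values[:12] = 30.0
        values[12:] = 10.0
        dose = lorp.DoseGrid(values, small_grid)
        mask = np.zeros(small_grid.shape, bool)
        mask[8:16, 4:12, 4:12] = True  # half below, half above the split
        s = lorp.Structure("s", mask, small_grid)
        assert metric_v(dose, s, 27.5, "cm3") == pytest.approx(s.volume_cm3 / 2)

    def test_level_above_max_is_zero(self, random_field):
        assert metric_v(*random_field, dose_level_gy=99.0) == 0.0


class TestMetricD:
    def test_uniform_dose(self, uniform_25):
        dose, mask = uniform_25
        assert metric_d(dose, mask, "mean") == 25.0
        assert metric_d(dose, mask, "1cm3") == 25.0

    def test_d1cm3_matches_sorting_oracle(self, random_field):
        dose, mask = random_field
        got = metric_d(dose, mask, "1cm3")
        d = np.sort(dose.values[mask.mask])[::-1]
        n = round(1.0 / mask.grid.voxel_volume_cm3)  # 125 voxels at 2 mm
        assert got == pytest.approx(d[n - 1])

    def test_small_mask_falls_back_with_warning(self, small_grid):
        dose = lorp.DoseGrid(np.full(small_grid.shape, 7.0), small_grid)
        mask = np.zeros(small_grid.shape, bool)
        mask[0, 0, :5] = True  # 0.04 cm3
        s = lorp.Structure("tiny", mask, small_grid)
        with pytest.warns(UserWarning, match="1 cm"):
            assert metric_d(dose, s, "1cm3") == 7.0


class TestClassifier:
    def test_all_ideal_is_per_protocol(self, criteria, ideal_criterion_values):
        ev = classify_plan(ideal_criterion_values, criteria)
        assert ev.overall == "per_protocol"
        assert ev.acceptable

    def test_near_ideal_is_acceptable(self, criteria, ideal_criterion_values):
        values = dict(ideal_criterion_values)
        values["ptv_v25gy"] = 92.0
        values["ptv_v23p75gy"] = 96.0
        ev = classify_plan(values, criteria)
        assert ev.overall == "acceptable"

    def test_target_underdose_is_unacceptable(self, criteria, ideal_criterion_values):
        """A daily PTV coverage of 88.67 % fails the 90 % variation bound."""
        values = dict(ideal_criterion_values)
        values["ptv_v25gy"] = 88.67
        ev = classify_plan(values, criteria)
        assert ev.overall == "unacceptable"
        assert not ev.acceptable

    def test_boundary_semantics(self, criteria, ideal_criterion_values):
        # at_least passes at equality; less_than fails at equality
        values = dict(ideal_criterion_values)
        values["ptv_v25gy"] = 95.0
        assert classify_plan(values, criteria).overall == "per_protocol"
        values["bladder_v25gy"] = 50.0
        assert classify_plan(values, criteria).overall == "acceptable"
        values["bladder_v25gy"] = 60.0
        assert classify_plan(values, criteria).overall == "unacceptable"

    def test_monotone_in_single_metric(self, criteria, ideal_criterion_values):
        """Improving one metric never downgrades the overall class."""
        order = {"unacceptable": 0, "acceptable": 1, "per_protocol": 2}
        values = dict(ideal_criterion_values)
        values["ptv_v25gy"] = 85.0
        values["bladder_v25gy"] = 55.0
        prev = -1
        for v25 in (85.0, 90.0, 95.0):
            values["ptv_v25gy"] = v25
            rank = order[classify_plan(values, criteria).overall]
            assert rank >= prev
            prev = rank

    def test_missing_metric_rejected(self, criteria, ideal_criterion_values):
        values = dict(ideal_criterion_values)
        del values["colon_v27p5gy"]
        with pytest.raises(ValueError, match="colon"):
            classify_plan(values, criteria)


class TestCriteriaIO:
    def test_default_table_shape(self, criteria):
        assert len(criteria) == 10
        assert len(criteria.structures()) == 7

    def test_round_trip(self, criteria, tmp_path):
        path = tmp_path / "criteria.yaml"
        lorp.save_criteria(criteria, path)
        again = lorp.load_criteria(path)
        assert again.rows == criteria.rows

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="looser"):
            CriterionRow(
                structure="bladder", metric="V", dose_level_gy=25.0,
                unit="percent", per_protocol=50, variation=40,
                direction="less_than",
            )
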