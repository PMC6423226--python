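"""qPCR standard curves, censoring rules and the absolute MOB census."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cumob.census import (
    CopyNumberTable,
    QPCRSample,
    StandardCurve,
    absolute_group_cells,
    apply_censoring,
    census_diagnostics,
    copies_per_litre,
    fit_standard_curve,
    lod_from_blanks,
    pmoa_cell_equivalents,
    pmoa_relative,
    quantify,
)
from cumob.errors import CurveError, MappingError, ParameterError, SampleSizeError


def _perfect_cp(copies, slope=-3.3219, intercept=40.0):
    return intercept + slope * np.log10(copies)


def _curve(slope=-3.3219, intercept=40.0, loq_copies=50.0):
    return StandardCurve(
        slope=slope, intercept=intercept, efficiency=10 ** (-1.0 / slope),
        r_squared=1.0, loq_copies=loq_copies,
        loq_cp=intercept + slope * np.log10(loq_copies),
    )


class TestStandardCurve:
    def test_perfect_doubling_efficiency(self):
        levels = [5e6, 5e4, 5e2]
        reps = [np.full(4, _perfect_cp(lv)) for lv in levels]
        curve = fit_standard_curve(levels, reps)
        assert curve.slope == pytest.approx(-3.3219, rel=1e-6)
        assert curve.efficiency == pytest.approx(2.000, abs=1e-3)
        assert curve.r_squared == pytest.approx(1.0)

    def test_efficiency_closed_form_for_shallower_slope(self):
        levels = [5e6, 5e4, 5e2]
        reps = [np.full(4, _perfect_cp(lv, slope=-3.6)) for lv in levels]
        curve = fit_standard_curve(levels, reps)
        assert curve.efficiency == pytest.approx(10 ** (1 / 3.6), rel=1e-6)
        assert curve.efficiency == pytest.approx(1.896, abs=1e-3)

    def test_positive_slope_is_curve_error(self):
        levels = [1e2, 1e4, 1e6]
        reps = [np.full(4, 20.0 + np.log10(lv)) for lv in levels]
        with pytest.raises(CurveError):
            fit_standard_curve(levels, reps)

    def test_loq_is_lowest_dilution_with_tight_quadruplicates(self):
        levels = [5e0, 5e2, 5e4, 5e6]
        reps = [np.full(4, _perfect_cp(lv)) for lv in levels]
        reps[0] = reps[0] + np.array([-1.0, 1.0, -1.0, 1.0])  # SD >> 0.5
        curve = fit_standard_curve(levels, reps)
        assert curve.loq_copies == 5e2

    def test_too_narrow_dilution_span_rejected(self):
        from cumob.errors import ValidationError

        levels = [1e3, 2e3, 4e3]
        reps = [np.full(4, _perfect_cp(lv)) for lv in levels]
        with pytest.raises(ValidationError):
            fit_standard_curve(levels, reps)


class TestCensoring:
    def _sample(self, cps, melts=None):
        cps = np.asarray(cps, dtype=float)
        melts = np.ones(cps.size, bool) if melts is None else np.asarray(melts)
        return QPCRSample("pmoA", 8.0, cps, melts)

    def test_replicate_spread_over_half_cycle_not_quantifiable(self):
        s = self._sample([31.0, 31.2, 31.9])
        assert apply_censoring(s, _curve(), lod_cp=37.0) == "not_quantifiable"

    def test_two_of_three_nondetected_not_quantifiable(self):
        s = self._sample([30.0, 38.0, 39.0])
        assert apply_censoring(s, _curve(), lod_cp=37.0) == "not_quantifiable"

    def test_clean_triplicate_quantified(self):
        s = self._sample([28.0, 28.1, 28.2])
        assert apply_censoring(s, _curve(), lod_cp=37.0) == "quantified"

    def test_all_nondetected_or_bad_melt_is_not_detected(self):
        s = self._sample([38.0, 39.0, 38.5])
        assert apply_censoring(s, _curve(), lod_cp=37.0) == "not_detected"
        s = self._sample([28.0, 28.1, 28.2], melts=[False, False, False])
        assert apply_censoring(s, _curve(), lod_cp=37.0) == "not_detected"

    def test_beyond_loq_estimated_by_extrapolation(self):
        curve = _curve(loq_copies=1000.0)
        cp_below_loq = curve.loq_cp + 1.0
        s = self._sample([cp_below_loq, cp_below_loq + 0.1, cp_below_loq - 0.1])
        assert apply_censoring(s, curve, lod_cp=45.0) == "estimated_below_LOQ"
        s2 = self._sample([cp_below_loq, cp_below_loq + 0.1, cp_below_loq - 0.1])
        assert (
            apply_censoring(s2, curve, lod_cp=45.0,
                            allow_extrapolation_below_loq=False)
            == "not_quantifiable"
        )

    def test_censoring_is_idempotent(self):
        s = self._sample([31.0, 31.2, 31.9])
        first = apply_censoring(s, _curve(), lod_cp=37.0)
        second = apply_censoring(s, _curve(), lod_cp=37.0)
        assert first == second

    def test_lod_from_blanks_takes_earliest_crossing(self):
        assert lod_from_blanks([38.2, 36.9, 39.5]) == 36.9
        assert lod_from_blanks([]) == 40.0


class TestQuantify:
    def test_intercept_is_single_copy(self):
        assert quantify(40.0, _curve()) == pytest.approx(1.0, rel=1e-6)

    def test_ten_cycles_earlier(self):
        assert quantify(30.0, _curve()) == pytest.approx(1023.6, rel=1e-3)

    def test_extrapolation_below_one_copy(self):
        assert quantify(43.3219, _curve()) == pytest.approx(0.1, rel=1e-3)

    def test_volume_bookkeeping_factor(self):
        # 2 uL template of a 100 uL extract from 1 L: factor 50
        assert copies_per_litre(1000.0, 2.0, 100.0, 1.0) == pytest.approx(5e4)
        assert copies_per_litre(0.0, 2.0, 100.0, 1.0) == 0.0
        with pytest.raises(ParameterError):
            copies_per_litre(1000.0, 0.0, 100.0, 1.0)


class TestAbsoluteCells:
    def test_single_group_conversion(self):
        cells = absolute_group_cells({"gamma_MOB": 0.10}, 1e9)
        assert cells["gamma_MOB"] == pytest.approx(1e8 / 5.8, rel=1e-12)

    def test_zero_fraction_zero_cells(self):
        assert absolute_group_cells({"alpha_MOB": 0.0}, 1e9)["alpha_MOB"] == 0.0

    def test_three_group_community(self):
        cells = absolute_group_cells(
            {"gamma_MOB": 0.10, "alpha_MOB": 0.01, "other": 0.89}, 1e9
        )
        assert cells["gamma_MOB"] == pytest.approx(1.7241e7, rel=1e-4)
        assert cells["alpha_MOB"] == pytest.approx(4.5455e6, rel=1e-4)
        assert cells["other"] == pytest.approx(2.11905e8, rel=1e-4)
        mob_rel = (cells["gamma_MOB"] + cells["alpha_MOB"]) / cells["_total"]
        assert mob_rel == pytest.approx(0.0932, abs=5e-4)

    def test_unknown_group_is_mapping_error(self):
        with pytest.raises(MappingError):
            absolute_group_cells({"archaea": 0.1}, 1e9)

    @given(scale=st.floats(0.1, 10), total=st.floats(1e6, 1e12))
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, scale, total):
        fr = {"gamma_MOB": 0.2, "other": 0.7}
        base = absolute_group_cells(fr, total)
        scaled = absolute_group_cells(fr, scale * total)
        for g in fr:
            assert scaled[g] == pytest.approx(scale * base[g], rel=1e-12)


class TestFunctionalGeneAbundance:
    def test_pmoa_relative_example(self):
        # 2e5 pmoA copies/L at 4.2e8 16S copies/L -> 1e5 cells / 1e8 cells
        rel = pmoa_relative(2e5, 4.2e8)
        assert rel == pytest.approx(1e-3, rel=1e-12)

    def test_zero_pmoa_zero_relative(self):
        assert pmoa_relative(0.0, 4.2e8) == 0.0

    def test_zero_16s_flagged_nan(self):
        assert np.isnan(pmoa_relative(1e5, 0.0))

    def test_mmox_single_copy_convention(self):
        assert pmoa_cell_equivalents(1e5, copies_per_cell=1.0) == 1e5
        rel = pmoa_relative(1e5, 4.2e8, copies_per_cell=1.0)
        assert rel == pytest.approx(1e-3, rel=1e-12)


class TestDiagnostics:
    def test_identical_profiles(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        assert census_diagnostics(x, x)["r_squared"] == pytest.approx(1.0)

    def test_affine_invariance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert census_diagnostics(x, 2 * x + 1)["r_squared"] == pytest.approx(1.0)

    def test_hand_pearson_value(self):
        # own oracle: r^2 = 49 / (2 * 258/9) = 0.854651..., cross-checked
        # against the covariance formula below
        x, y = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 9.0])
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        expected = sxy**2 / (np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert expected == pytest.approx(0.854651, abs=1e-6)
        assert census_diagnostics(x, y)["r_squared"] == pytest.approx(expected, rel=1e-12)

    def test_constant_series_undefined(self):
        x = np.array([1.0, 1.0, 1.0])
        assert census_diagnostics(x, np.array([1.0, 2.0, 3.0]))["r_squared"] is None

    def test_too_few_matched_depths(self):
        with pytest.raises(SampleSizeError):
            census_diagnostics(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_pmoa_mmox_ratio(self):
        pr = np.array([0.1, 0.2, 0.3])
        d = census_diagnostics(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.1, 2.9]),
            pmoa_rel=pr, mmox_rel=pr / 160.0,
        )
        assert d["mean_pmoa_to_mmox_ratio"] == pytest.approx(160.0, rel=1e-12)


def test_copy_number_table_defaults():
    ct = CopyNumberTable()
    assert ct["gamma_MOB"] == 5.8
    assert ct["alpha_MOB"] == 2.2
    assert ct["other"] == 4.2
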