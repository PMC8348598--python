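"""Calibration fitting, isotope correction and concentration recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from sweatlipidomics.preprocessing import subtract_blank
from sweatlipidomics.quantitation import (
    IsotopeParams,
    class_composition,
    curves_from_table,
    fit_calibration,
    isotope_correction_factor,
    quantify,
)
from sweatlipidomics.synthetic import GeneratorParams, generate_dataset


class TestFitCalibration:
    def test_exact_line(self):
        curve = fit_calibration([1, 2, 3, 4], [2, 4, 6, 8])
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r2 == pytest.approx(1.0)
        assert curve.valid_range == (1.0, 4.0)

    def test_ols_closed_form(self):
        # slope = Sxy/Sxx = 3.9/2, intercept = ybar - slope*xbar
        curve = fit_calibration([1, 2, 3], [2.1, 3.9, 6.0])
        assert curve.slope == pytest.approx(1.95)
        assert curve.intercept == pytest.approx(4.0 - 1.95 * 2.0)

    def test_weighted_fit_matches_ols_on_exact_line(self):
        for w in ("1/x", "1/x2"):
            curve = fit_calibration([1, 2, 4, 8], [3, 6, 12, 24], weighting=w)
            assert curve.slope == pytest.approx(3.0)
            assert curve.intercept == pytest.approx(0.0, abs=1e-9)
            assert curve.r2 == pytest.approx(1.0)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([1, 1], [2, 2.2])


class TestIsotopeCorrection:
    P13 = 0.0107

    @staticmethod
    def _monoisotopic_fraction(n_carbons, p13):
        """Independent binomial isotope-pattern oracle: P(zero 13C atoms)."""
        from scipy.stats import binom
        return binom.pmf(0, n_carbons, p13)

    def test_equal_carbons_is_unity(self):
        assert isotope_correction_factor(24, 24) == 1.0

    def test_against_binomial_oracle(self):
        for nca, ncs in [(40, 24), (10, 55), (0, 24), (63, 63)]:
            oracle = (self._monoisotopic_fraction(ncs, self.P13)
                      / self._monoisotopic_fraction(nca, self.P13))
            assert isotope_correction_factor(nca, ncs) == pytest.approx(
                oracle, abs=1e-9)

    def test_forty_vs_twentyfour(self):
        assert isotope_correction_factor(40, 24) == pytest.approx(1.188, abs=2e-3)

    def test_reciprocal_property(self):
        f = isotope_correction_factor
        assert f(17, 42) * f(42, 17) == pytest.approx(1.0, rel=1e-12)

    def test_zero_carbon_boundary(self):
        assert isotope_correction_factor(0, 24) == pytest.approx(
            (1 - self.P13) ** 24)

    def test_invalid_abundance(self):
        with pytest.raises(ValueError):
            IsotopeParams(p13=1.2)


class TestQuantify:
    def test_simple_arithmetic(self):
        from sweatlipidomics.quantitation import CalibrationCurve
        curve = CalibrationCurve(
            standard_label="FA 20:4", class_code="FA", standard_carbons=20,
            concentrations=np.array([1.0, 10.0]), areas=np.array([2.0, 20.0]),
            slope=2.0, intercept=0.0, r2=1.0)
        areas = pd.DataFrame({"FA 20:4": [10.0, 100.0]}, index=["s1", "s2"])
        conc, mask, report = quantify(areas, {"FA": curve})
        assert conc.loc["s1", "FA 20:4"] == pytest.approx(5.0)
        # 100/2 = 50 exceeds the top level -> masked
        assert np.isnan(conc.loc["s2", "FA 20:4"])
        assert bool(mask.loc["s2", "FA 20:4"])
        assert report["n_out_of_range"] == 1

    def test_missing_class_curve_skips(self):
        areas = pd.DataFrame({"PC 34:1": [1.0]}, index=["s1"])
        conc, _, report = quantify(areas, {})
        assert report["skipped_analytes"] == ["PC 34:1"]
        assert conc["PC 34:1"].isna().all()

    def test_zero_noise_inversion(self, noiseless_params):
        """With all noise off, quantitation inverts the generator exactly."""
        table, truth = generate_dataset(noiseless_params)
        curves = curves_from_table(table, truth.cal_concs)
        conc, _, _ = quantify(table, curves)
        ok = conc.notna()
        assert ok.to_numpy().mean() > 0.95
        rel = ((conc - truth.concentrations).abs() / truth.concentrations)[ok]
        assert np.nanmax(rel.to_numpy()) < 1e-6


class TestClassComposition:
    def test_single_class(self):
        conc = pd.DataFrame({"FA 16:0": [1.0, 2.0]})
        comp = class_composition(conc)
        assert comp.loc["FA", "percent_of_total"] == pytest.approx(100.0)

    def test_three_to_one_split(self):
        conc = pd.DataFrame({"FA 16:0": [3.0], "PC 34:1": [1.0]})
        comp = class_composition(conc)
        assert comp.loc["FA", "percent_of_total"] == pytest.approx(75.0)
        assert comp.loc["PC", "percent_of_total"] == pytest.approx(25.0)
        assert comp["percent_of_total"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_recovery_against_generator_truth(self):
        """Recovered class percentages track the truth within 5 % relative.

        Drift is off (drift correction is a separate stage); noise and all
        biological variance terms are at their defaults.  Truth sums run
        over the same quantified cells, since out-of-range exclusion is the
        method's own rule.
        """
        params = GeneratorParams(seed=11, drift_mode="none")
        table, truth = generate_dataset(params)
        analytes, _ = subtract_blank(table.select_labels(table.analyte_labels()))
        conc, _, _ = quantify(analytes, curves_from_table(table, truth.cal_concs))
        comp = class_composition(conc)
        diluted = truth.concentrations.mul(truth.dilution, axis=0)
        diluted = diluted[conc.columns].where(conc.notna())
        truth_sums = diluted.sum().groupby(truth.lipid_classes).sum()
        truth_pct = truth_sums / truth_sums.sum() * 100
        rel_err = (comp["percent_of_total"] - truth_pct).abs() / truth_pct
        assert rel_err.max() < 0.05

    def test_concentration_dispersion_spans_four_orders(self, default_dataset):
        table, truth = default_dataset
        conc, _, _ = quantify(table, curves_from_table(table, truth.cal_concs))
        vals = conc.to_numpy()
        vals = vals[np.isfinite(vals) & (vals > 0)]
        assert np.log10(vals.max() / vals.min()) >= 4.0

    def test_all_missing_rejected(self):
        conc = pd.DataFrame({"FA 16:0": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            class_composition(conc)
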