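"""Z′, normalization, 4PL, Cheng-Prusoff, FI QC and counter-screen verdicts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylfp import (PlateRead, ValidationError, cheng_prusoff_ki,
                      counter_screen_verdict, fit_ic50, percent_inhibition,
                      qc_fluorescence, z_prime)

from helpers import four_pl


def mini_plate(fi_sample=10000.0):
    records = []
    for i in range(4):
        records.append(dict(well=f"A{i+1}", mp=150.0 + i * 0.1, fi=10000.0,
                            role="neg_ctrl", compound_id="DMSO",
                            compound_conc=0.0))
        records.append(dict(well=f"B{i+1}", mp=60.0 + i * 0.1, fi=10000.0,
                            role="pos_ctrl", compound_id="DMSO",
                            compound_conc=0.0))
    records.append(dict(well="C1", mp=100.0, fi=fi_sample, role="sample",
                        compound_id="CPD1", compound_conc=10.0))
    return PlateRead.from_records(records)


class TestZPrime:
    def test_zero_variance_gives_one(self):
        assert z_prime([10.0, 10.0], [200.0, 200.0]) == 1.0

    def test_textbook_arithmetic(self):
        # window 100, both SDs 5 → 1 − 30/100 = 0.70
        pos = [100.0 - 5.0, 100.0 + 5.0]
        neg = [200.0 - 5.0, 200.0 + 5.0]
        sd = np.std(pos, ddof=1)
        assert z_prime(pos, neg) == pytest.approx(1.0 - 6.0 * sd / 100.0)

    def test_uses_sample_standard_deviation(self):
        pos = [98.0, 100.0, 102.0]
        neg = [198.0, 200.0, 202.0]
        expected = 1.0 - 3.0 * (np.std(pos, ddof=1) + np.std(neg, ddof=1)) / 100
        assert z_prime(pos, neg) == pytest.approx(expected, rel=1e-12)

    def test_coincident_means_return_sentinel(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert z_prime([10.0, 11.0], [10.0, 11.0]) == -math.inf

    @given(a=st.floats(-10, 10).filter(lambda v: abs(v) > 1e-3),
           b=st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b):
        pos = np.array([100.0, 104.0, 97.0, 99.0])
        neg = np.array([200.0, 201.0, 196.0, 203.0])
        assert z_prime(a * pos + b, a * neg + b) == pytest.approx(
            z_prime(pos, neg), rel=1e-9)

    def test_needs_two_values_per_group(self):
        with pytest.raises(ValidationError):
            z_prime([1.0], [2.0, 3.0])


class TestPercentInhibition:
    def test_control_anchors_and_midpoint(self):
        assert percent_inhibition(60.0, 150.0, 60.0) == pytest.approx(100.0)
        assert percent_inhibition(150.0, 150.0, 60.0) == pytest.approx(0.0)
        assert percent_inhibition(105.0, 150.0, 60.0) == pytest.approx(50.0)

    def test_degenerate_controls_rejected(self):
        with pytest.raises(ValidationError):
            percent_inhibition(10.0, 100.0, 100.0)


class TestFitIc50:
    def test_noiseless_recovery_of_known_curve(self):
        # the potency scale of a weak natural-product hit (~67 µM)
        doses = np.geomspace(1.0, 1000.0, 9)
        y = four_pl(doses, bottom=0.0, top=100.0, ic50=67.0, hill=1.0)
        fit = fit_ic50(doses, y)
        assert fit.ic50 == pytest.approx(67.0, rel=1e-4)
        assert fit.hill == pytest.approx(1.0, rel=1e-3)
        assert fit.bottom < fit.top
        assert fit.r_squared > 0.999999

    def test_steep_and_shallow_hill_slopes_recovered(self):
        doses = np.geomspace(0.1, 100.0, 11)
        for hill in (0.5, 2.0):
            y = four_pl(doses, bottom=5.0, top=95.0, ic50=3.0, hill=hill)
            fit = fit_ic50(doses, y)
            assert fit.ic50 == pytest.approx(3.0, rel=1e-3)
            assert fit.hill == pytest.approx(hill, rel=1e-2)

    def test_fitted_curve_passes_midpoint_at_ic50(self):
        doses = np.geomspace(0.1, 100.0, 9)
        y = four_pl(doses, bottom=0.0, top=80.0, ic50=5.0, hill=1.0)
        fit = fit_ic50(doses, y)
        mid = four_pl(fit.ic50, fit.bottom, fit.top, fit.ic50, fit.hill)
        assert mid == pytest.approx((fit.top + fit.bottom) / 2.0, rel=1e-9)

    def test_flat_response_flagged_inactive(self):
        doses = np.geomspace(0.1, 100.0, 7)
        fit = fit_ic50(doses, np.zeros(7))
        assert math.isnan(fit.ic50)
        assert "inactive" in fit.qc_flags

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            fit_ic50([1, 2, 3, 4], [0, 10, 50, 90])
        with pytest.raises(ValidationError):
            fit_ic50([1, 1.5, 2, 2.5, 3], [0, 10, 50, 70, 90])


class TestChengPrusoff:
    def test_exact_line_recovers_ki_and_slope(self):
        ki, km = 2.0, 1.0
        pairs = [(s, ki * (1 + s / km)) for s in (0.5, 1.0, 2.0, 4.0)]
        res = cheng_prusoff_ki(pairs)
        assert res.ki == pytest.approx(2.0, rel=1e-12)
        assert res.slope == pytest.approx(2.0, rel=1e-12)
        assert res.km == pytest.approx(1.0, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert not res.qc_flags

    def test_negative_intercept_flagged(self):
        res = cheng_prusoff_ki([(1.0, 1.0), (2.0, 4.0), (3.0, 7.0)])
        assert res.ki < 0
        assert "negative_intercept" in res.qc_flags

    def test_needs_three_points(self):
        with pytest.raises(ValidationError):
            cheng_prusoff_ki([(1.0, 2.0), (2.0, 3.0)])


class TestQcFluorescence:
    def test_reference_fi_not_flagged(self):
        flags = qc_fluorescence(mini_plate(fi_sample=10000.0))
        assert not flags.loc["C1"]

    def test_half_fi_flagged(self):
        assert qc_fluorescence(mini_plate(fi_sample=5000.0)).loc["C1"]

    def test_25_percent_change_is_below_the_30_percent_rule(self):
        assert not qc_fluorescence(mini_plate(fi_sample=7500.0)).loc["C1"]
        assert qc_fluorescence(mini_plate(fi_sample=6900.0)).loc["C1"]


class TestCounterScreenVerdict:
    def test_exact_reference_is_true_hit(self):
        assert counter_screen_verdict(80.0, 100.0, 100.0, 2.0) == "true_hit"

    def test_shifted_counter_signal_is_false_positive(self):
        assert counter_screen_verdict(80.0, 110.0, 100.0, 2.0) == \
            "false_positive"
        assert counter_screen_verdict(80.0, 90.0, 100.0, 2.0) == \
            "false_positive"

    def test_missing_counter_data_is_untested(self):
        assert counter_screen_verdict(80.0, math.nan, 100.0, 2.0) == "untested"


class TestPlateRead:
    def test_rejects_out_of_bounds_wells_and_duplicates(self):
        with pytest.raises(ValidationError, match="Q1"):
            PlateRead.from_records([
                dict(well="Q1", mp=1.0, fi=1.0, role="sample",
                     compound_id="x", compound_conc=1.0)])
        with pytest.raises(ValidationError, match="duplicate"):
            PlateRead.from_records([
                dict(well="A1", mp=1.0, fi=1.0, role="sample",
                     compound_id="x", compound_conc=1.0),
                dict(well="A1", mp=2.0, fi=1.0, role="sample",
                     compound_id="y", compound_conc=1.0)])

    def test_rejects_nonpositive_fi_on_measured_wells(self):
        with pytest.raises(ValidationError, match="FI"):
            PlateRead.from_records([
                dict(well="A1", mp=1.0, fi=0.0, role="sample",
                     compound_id="x", compound_conc=1.0)])
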