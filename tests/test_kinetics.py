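"""Reaction simulation vs the Lambert-W oracle, fits, conversion formula."""

import numpy as np
import pytest
from scipy.optimize import brentq

from methylfp import (Inhibitor, ReactionSystem, ReporterSpec,
                      TimeCourseDesign, ValidationError,
                      effective_rate_factor, estimate_conversion, fit_km_kcat,
                      run_time_course, simulate_conversion)

from helpers import lambertw_progress


def system(**overrides):
    base = dict(km_substrate=0.1, kcat=0.5, enzyme_total=0.02,
                substrate_total=0.02, cofactor_conc=1.0, cofactor_km=0.0)
    base.update(overrides)
    return ReactionSystem(**base)


class TestSimulateConversion:
    def test_zero_time_and_zero_enzyme_give_no_conversion(self):
        assert simulate_conversion(system(), 0.0) == 0.0
        assert simulate_conversion(system(enzyme_total=0.0), 60.0) == 0.0

    def test_matches_lambertw_closed_form(self):
        # Km = 1 µM, kcat = 1/min, E = 20 nM, S0 = 20 nM
        sys = system(km_substrate=1.0, kcat=1.0, enzyme_total=0.020,
                     substrate_total=0.020)
        times = np.array([1.0, 10.0, 60.0, 300.0])
        frac = simulate_conversion(sys, times)
        s_expected = lambertw_progress(0.020, 1.0, 1.0 * 0.020, times)
        np.testing.assert_allclose(frac, (0.020 - s_expected) / 0.020,
                                   rtol=1e-8, atol=1e-8)

    def test_monotone_in_time_and_enzyme(self):
        times = np.linspace(0, 120, 25)
        frac = simulate_conversion(system(), times)
        assert np.all(np.diff(frac) >= -1e-12)
        assert frac[-1] <= 1.0
        double = simulate_conversion(system(enzyme_total=0.04), times)
        assert np.all(double - frac >= -1e-10)

    def test_saturating_inhibitor_stops_the_reaction(self):
        inh = Inhibitor("noncompetitive", ki=1.0, conc=1e12)
        assert simulate_conversion(system(inhibitor=inh), 600.0) < 1e-9

    def test_cofactor_saturation_scales_rate(self):
        fast = simulate_conversion(system(cofactor_km=0.0), 5.0)
        half = simulate_conversion(
            system(cofactor_km=1.0, cofactor_conc=1.0), 5.0)
        slower = simulate_conversion(
            system(cofactor_km=1.0, cofactor_conc=0.1), 5.0)
        assert fast > half > slower

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            simulate_conversion(system(), -1.0)


class TestEffectiveRateFactor:
    KW = dict(substrate_conc=0.02, km_substrate=0.1, cofactor_conc=1.0,
              cofactor_km=1.0)

    def test_no_inhibitor_is_unity(self):
        assert effective_rate_factor(None, **self.KW) == 1.0
        zero = Inhibitor("cofactor_competitive", ki=1.0, conc=0.0)
        assert effective_rate_factor(zero, **self.KW) == 1.0

    def test_noncompetitive_at_ki_halves_vmax(self):
        inh = Inhibitor("noncompetitive", ki=2.0, conc=2.0)
        assert effective_rate_factor(inh, **self.KW) == pytest.approx(0.5)

    def test_competitive_ic50_at_km_equals_twice_ki(self):
        # Cheng-Prusoff: rate halves at [I] = Ki(1+[S]/Km) = 2·Ki when [S]=Km
        ki = 3.0
        kw = dict(substrate_conc=0.1, km_substrate=0.1, cofactor_conc=1.0,
                  cofactor_km=1.0)
        ic50 = brentq(
            lambda i: effective_rate_factor(
                Inhibitor("substrate_competitive", ki=ki, conc=i), **kw) - 0.5,
            1e-6, 1e4)
        assert ic50 == pytest.approx(2.0 * ki, rel=1e-9)

    def test_unknown_mechanism_rejected(self):
        with pytest.raises(ValidationError):
            Inhibitor("uncompetitive", ki=1.0, conc=1.0)


class TestRunTimeCourse:
    REPORTER = ReporterSpec(15.0, 0.15, mp_max=150.0, mp_min=50.0)

    def design(self):
        return TimeCourseDesign(start_offsets=[0, 10, 20, 30, 40, 50, 60],
                                total_span=60.0,
                                enzyme_concs=[0.01, 0.02, 0.04])

    def test_zero_minute_wells_sit_at_substrate_baseline(self):
        design = TimeCourseDesign([60.0], 60.0, [0.04])
        table = run_time_course(system(), design, self.REPORTER, 1.5)
        baseline = run_time_course(
            system(enzyme_total=0.0), design, self.REPORTER, 1.5)
        assert table["mp"].iloc[0] == pytest.approx(baseline["mp"].iloc[0])
        assert table["conversion"].iloc[0] == 0.0

    def test_mp_monotone_in_reaction_time_and_enzyme(self):
        table = run_time_course(system(), self.design(), self.REPORTER, 1.5)
        for _, grp in table.groupby("enzyme_conc"):
            g = grp.sort_values("reaction_time")
            assert np.all(np.diff(g["mp"]) >= -1e-9)
        at_60 = table[table["reaction_time"] == 60.0].sort_values("enzyme_conc")
        assert np.all(np.diff(at_60["mp"]) >= -1e-9)

    def test_demethylation_direction_inverts_the_signal(self):
        table = run_time_course(system(), self.design(), self.REPORTER, 1.5,
                                direction="demethylation")
        for _, grp in table.groupby("enzyme_conc"):
            g = grp.sort_values("reaction_time")
            assert np.all(np.diff(g["mp"]) <= 1e-9)

    def test_long_time_limit_approaches_product_plateau(self):
        design = TimeCourseDesign([0.0], 2000.0, [0.1])
        table = run_time_course(system(), design, self.REPORTER, 1.5)
        from methylfp import LigandMixture, fp_signal, solve_equilibrium
        plateau = fp_signal(self.REPORTER, solve_equilibrium(
            self.REPORTER, LigandMixture(0.02, 1.0), 1.5))
        assert table["mp"].iloc[0] == pytest.approx(plateau, abs=0.1)

    def test_offsets_outside_span_rejected(self):
        with pytest.raises(ValidationError):
            TimeCourseDesign([70.0], 60.0, [0.02])


class TestFitKmKcat:
    def test_noiseless_recovery_is_exact(self):
        km, vmax = 2.0, 0.04
        s = np.geomspace(0.2, 20.0, 8)
        fit = fit_km_kcat(zip(s, vmax * s / (km + s)), enzyme_total=0.02)
        assert fit.km == pytest.approx(km, rel=1e-6)
        assert fit.vmax == pytest.approx(vmax, rel=1e-6)
        assert fit.kcat == pytest.approx(vmax / 0.02, rel=1e-6)
        assert not fit.flags

    def test_noisy_recovery_within_ten_percent_median(self, rng):
        km, vmax = 2.0, 0.04
        s = np.geomspace(0.2, 20.0, 8)
        v_true = vmax * s / (km + s)
        errs = []
        for _ in range(200):
            v = v_true * (1.0 + rng.normal(0.0, 0.05, s.size))
            errs.append(abs(fit_km_kcat(zip(s, v)).km - km) / km)
        assert np.median(errs) < 0.10

    def test_unidentifiable_range_is_flagged(self):
        km, vmax = 50.0, 1.0
        s = np.geomspace(0.01, 0.1, 6)  # everything far below Km
        fit = fit_km_kcat(zip(s, vmax * s / (km + s)))
        assert "poorly_constrained" in fit.flags

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_km_kcat([(1.0, 0.1)] * 6)


class TestEstimateConversion:
    def test_formula_endpoints_and_midpoint(self):
        assert estimate_conversion(80.0, 80.0, 140.0).percent == 0.0
        assert estimate_conversion(140.0, 80.0, 140.0).percent == 100.0
        assert estimate_conversion(110.0, 80.0, 140.0).percent == 50.0

    def test_raw_value_reported_next_to_clamp(self):
        est = estimate_conversion(150.0, 80.0, 140.0)
        assert est.percent == 100.0
        assert est.raw == pytest.approx(116.6666667)

    def test_degenerate_controls_rejected(self):
        with pytest.raises(ValidationError):
            estimate_conversion(100.0, 90.0, 90.0)
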