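"""Secondary PK parameters: closed-form oracles and cross-method checks."""

import numpy as np
import pytest

from ritpk import (
    CompartmentTopology,
    DoseEvent,
    FitOptions,
    ParameterVector,
    auc,
    aumc,
    clearance,
    cmax,
    fit,
    mrt,
    mrt_model,
    simulate,
    summarize_fit,
    terminal_half_life,
    terminal_half_life_model,
    vd_from_fit,
)
from ritpk.model import BLOOD
from ritpk.pkparams import FOUR_DAYS_MIN, terminal_slope


def _mono(kel):
    top = CompartmentTopology("mono", (BLOOD,), (), (BLOOD,))
    return top, ParameterVector(Vd_mL=1000.0, k_el={BLOOD: kel})


class TestAUC:
    def test_exponential_closed_form(self):
        t = np.linspace(0, 3000, 6001)
        c = np.exp(-0.01 * t)
        got = auc(t, c, extrapolate=True)
        assert got == pytest.approx(100.0, rel=1e-4)

    def test_constant_curve(self):
        assert auc([0, 10], [2.0, 2.0]) == pytest.approx(20.0)

    def test_cumulative_windows_are_ordered(self):
        t = np.linspace(0, 7 * 24 * 60, 400)
        c = np.exp(-2e-4 * t) * (1 + 0.2 * np.sin(t / 500))
        a4 = auc(t, c, t_end=FOUR_DAYS_MIN)
        a7 = auc(t, c)
        a_tot = auc(t, c, extrapolate=True)
        assert a4 <= a7 <= a_tot

    def test_window_boundary_interpolated(self):
        # integral of exp(-0.001 t) over [0, 500] with grid points at 0/1000
        t = np.array([0.0, 1000.0])
        c = np.exp(-0.001 * t)
        got = auc(t, c, t_end=500.0)
        assert got == pytest.approx((1 - np.exp(-0.5)) / 0.001, rel=1e-6)


class TestHalfLifeAndMRT:
    def test_half_life_closed_forms(self):
        t = np.linspace(0, 50000, 200)
        c = np.exp(-0.000138 * t)
        assert terminal_half_life(t, c) == pytest.approx(
            np.log(2) / 0.000138 / 60.0, rel=1e-6
        )
        c2 = np.exp(-0.01 * t[:50])
        # ln2/k in minutes = 69.31
        lam, _ = terminal_slope(t[:50], c2)
        assert np.log(2) / lam == pytest.approx(69.31, rel=1e-3)

    def test_model_mode_half_life_matches_eigenvalue(self):
        top, p = _mono(0.000138)
        assert terminal_half_life_model(top, p) == pytest.approx(
            np.log(2) / 0.000138 / 60.0, rel=1e-12
        )

    def test_curve_and_model_half_life_agree(self, topology, f1_params):
        t = np.geomspace(96 * 60.0, 400 * 60.0, 60)
        course = simulate(topology, f1_params, DoseEvent(1000.0), t)
        hl_curve = terminal_half_life(t, course.blood_concentration(f1_params.Vd_mL))
        hl_model = terminal_half_life_model(topology, f1_params)
        assert hl_curve == pytest.approx(hl_model, rel=0.02)

    def test_mrt_one_compartment_closed_form(self):
        kel = 0.000146
        top, p = _mono(kel)
        t = np.geomspace(1, 60000, 400)
        course = simulate(top, p, DoseEvent(1000.0), t)
        got = mrt(t, course.blood_concentration(p.Vd_mL))
        assert got == pytest.approx(1 / kel / 60.0, rel=1e-3)  # ≈ 114.1 h
        assert mrt_model(top, p) == pytest.approx(1 / kel / 60.0, rel=1e-12)

    def test_mrt_invariant_to_dose(self):
        top, p = _mono(2e-4)
        t = np.geomspace(1, 80000, 300)
        c1 = simulate(top, p, DoseEvent(100.0), t).blood_concentration(p.Vd_mL)
        c2 = simulate(top, p, DoseEvent(2000.0), t).blood_concentration(p.Vd_mL)
        assert mrt(t, c1) == pytest.approx(mrt(t, c2), rel=1e-10)


class TestClearanceVd:
    def test_unit_example(self):
        assert clearance(1000.0, 1000.0) == pytest.approx(1.0)

    def test_implied_elimination_rate_from_cohort_means(self):
        # CL/Vd with the cohort blood means gives the implied first-order
        # elimination constant
        assert 1.03 / 4131.0 == pytest.approx(2.49e-4, rel=0.002)

    def test_dose_over_auc_equals_vd_kel_for_blood_elimination(
        self, topology, f1_params
    ):
        t = np.geomspace(0.1, 3e5, 4000)
        course = simulate(topology, f1_params, DoseEvent(1000.0), t)
        c = course.blood_concentration(f1_params.Vd_mL)
        auc_total = auc(t, c, extrapolate=True)
        cl = clearance(1000.0, auc_total)
        assert cl == pytest.approx(
            f1_params.Vd_mL * f1_params.k_el[BLOOD], rel=5e-3
        )

    def test_zero_auc_rejected(self):
        with pytest.raises(ValueError):
            clearance(100.0, 0.0)


class TestCmax:
    def test_monotone_decreasing_peaks_at_first_point(self):
        t = np.linspace(1, 100, 10)
        c = 5.0 * np.exp(-0.01 * t)
        v, tm = cmax(t, c)
        assert tm == t[0] and v == pytest.approx(c[0])

    def test_rising_falling_interior_peak(self):
        t = np.linspace(0, 10, 101)
        c = t * np.exp(-t)
        v, tm = cmax(t, c)
        assert tm == pytest.approx(1.0, abs=0.06)

    def test_bolus_blood_cmax_is_dose_over_vd(self):
        top, p = _mono(1e-4)
        t = np.geomspace(1e-3, 1e4, 50)
        course = simulate(top, p, DoseEvent(500.0), t)
        v, tm = cmax(t, course.blood_concentration(p.Vd_mL))
        assert v == pytest.approx(500.0 / p.Vd_mL, rel=1e-4)
        assert tm == t[0]


class TestSummary:
    def test_summary_units_and_orderings(
        self, topology, dense_noise_free_dataset, fast_fit_options, f1_params
    ):
        res = fit(topology, dense_noise_free_dataset, fast_fit_options)
        summary = summarize_fit(res, dense_noise_free_dataset)
        b = summary.blood
        assert b["AUCcum_4d_ug_min_mL"] <= b["AUCcum_7d_ug_min_mL"] <= b["AUC_total_ug_min_mL"]
        assert vd_from_fit(res) == pytest.approx(f1_params.Vd_mL, rel=0.01)
        # CL = Vd·kel for blood-only elimination; the 7-day truncation of the
        # summary grid leaves a small extrapolation bias in the NCA tail
        assert b["CL_mL_min"] == pytest.approx(
            f1_params.Vd_mL * f1_params.k_el[BLOOD], rel=0.05
        )
        for comp, d in summary.compartments.items():
            assert d["AUCcum_4d_ug_min_mL"] <= d["AUCcum_7d_ug_min_mL"]
            assert d["Cmax_ug_mL"] >= 0.0
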