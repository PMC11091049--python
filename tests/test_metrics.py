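"""Step-3 decomposition, AUC quadrature, ICPR and absolute bioavailability."""

import numpy as np
import pytest

from insep import (
    AnalyteSeries,
    DEFAULT_UNITS,
    DomainError,
    EndogenousPrediction,
    InsulinKineticParams,
    UnitConversionTable,
    absolute_bioavailability,
    bateman_concentration,
    icpr_profile,
    subtract_exogenous,
    trapezoid_auc,
)


def make_pred(times, values):
    return EndogenousPrediction(times=np.asarray(times, float), iendo=np.asarray(values, float))


class TestSubtraction:
    def test_self_subtraction_is_zero(self, paper_grid):
        vals = np.linspace(50, 300, paper_grid.size)
        total = AnalyteSeries("insulin", paper_grid, vals)
        res = subtract_exogenous(total, make_pred(paper_grid, vals))
        np.testing.assert_array_equal(res.i_exo, 0.0)
        assert res.n_negative_iexo == 0

    def test_known_exogenous_truth_recovered(self, paper_grid):
        endo = np.linspace(50, 200, paper_grid.size)
        exo = 400.0 * np.exp(-paper_grid / 40.0) * (paper_grid / 15.0)
        total = AnalyteSeries("insulin", paper_grid, endo + exo)
        res = subtract_exogenous(total, make_pred(paper_grid, endo))
        np.testing.assert_allclose(res.i_exo, exo, rtol=1e-12, atol=1e-12)

    def test_conservation_to_machine_precision(self, paper_grid):
        rng = np.random.default_rng(0)
        endo = rng.uniform(40, 300, paper_grid.size)
        total = AnalyteSeries("insulin", paper_grid, rng.uniform(50, 600, paper_grid.size))
        res = subtract_exogenous(total, make_pred(paper_grid, endo))
        np.testing.assert_allclose(res.i_endo + res.i_exo, res.i_total, rtol=1e-15)

    def test_negative_values_retained_and_counted(self, paper_grid):
        endo = np.full(paper_grid.size, 100.0)
        total_vals = np.full(paper_grid.size, 150.0)
        total_vals[3] = 80.0  # endo exceeds total at one time
        total = AnalyteSeries("insulin", paper_grid, total_vals)
        res = subtract_exogenous(total, make_pred(paper_grid, endo))
        assert res.i_exo[3] == pytest.approx(-20.0)
        assert res.n_negative_iexo == 1

    def test_grid_mismatch_rejected(self, paper_grid):
        total = AnalyteSeries("insulin", paper_grid, np.full(paper_grid.size, 100.0))
        with pytest.raises(Exception):
            subtract_exogenous(total, make_pred(paper_grid[:-1], np.full(paper_grid.size - 1, 90.0)))


class TestTrapezoidAuc:
    def test_flat_series_rectangle(self):
        t = np.array([0.0, 60.0, 120.0])
        assert trapezoid_auc(t, np.full(3, 5.0)) == pytest.approx(5.0 * 120.0)

    def test_flat_series_supra_basal_is_zero(self):
        t = np.array([0.0, 60.0, 120.0])
        assert trapezoid_auc(t, np.full(3, 5.0), supra_basal=True) == 0.0

    def test_triangle(self):
        t = np.array([0.0, 60.0, 120.0])
        assert trapezoid_auc(t, np.array([0.0, 100.0, 0.0])) == pytest.approx(6000.0)

    def test_sub_interval_with_interpolation(self):
        t = np.array([0.0, 60.0, 120.0])
        v = np.array([0.0, 100.0, 0.0])
        assert trapezoid_auc(t, v, t_start=30.0, t_end=90.0) == pytest.approx(
            0.5 * (50 + 100) * 30 + 0.5 * (100 + 50) * 30
        )

    def test_empty_interval_rejected(self):
        with pytest.raises(DomainError):
            trapezoid_auc(np.array([0.0, 10.0]), np.array([1.0, 1.0]), t_start=5.0, t_end=5.0)

    def test_nonnegative_supra_basal_profile_gives_nonnegative_sauc(self):
        t = np.linspace(0, 360, 9)
        v = 100.0 + 50.0 * np.sin(np.pi * t / 360.0)  # never below its t=0 value
        assert trapezoid_auc(t, v, supra_basal=True) >= 0.0


class TestIcpr:
    def test_proportional_profiles_give_constant_ratio(self, paper_grid):
        cp_vals = np.linspace(400, 1200, paper_grid.size)
        cp = AnalyteSeries("cpeptide", paper_grid, cp_vals)
        ratio = icpr_profile(make_pred(paper_grid, 0.2 * cp_vals), cp)
        np.testing.assert_allclose(ratio, 0.2, rtol=1e-12)

    def test_steady_state_closed_form(self, cp_params, paper_grid):
        """At joint steady state with constant secretion S the ratio is
        (S/(n V_I)) / (S/(k01 V_CP1)) = k01 V_CP1 / (n V_I)."""
        ins = InsulinKineticParams(V_I=15.68, n=0.12)
        s = 200.0
        iendo = make_pred(paper_grid, np.full(paper_grid.size, s / (ins.n * ins.V_I)))
        cp = AnalyteSeries(
            "cpeptide", paper_grid,
            np.full(paper_grid.size, s / (cp_params.k01 * cp_params.V_CP1)),
        )
        ratio = icpr_profile(iendo, cp)
        expected = cp_params.k01 * cp_params.V_CP1 / (ins.n * ins.V_I)
        np.testing.assert_allclose(ratio, expected, rtol=1e-12)

    def test_zero_cpeptide_yields_missing_with_warning(self, paper_grid):
        cp_vals = np.full(paper_grid.size, 500.0)
        cp_vals[4] = 0.0
        cp = AnalyteSeries("cpeptide", paper_grid, cp_vals)
        with pytest.warns(UserWarning, match="zero C-peptide"):
            ratio = icpr_profile(make_pred(paper_grid, np.full(paper_grid.size, 60.0)), cp)
        assert np.isnan(ratio[4]) and np.isfinite(ratio[0])


class TestBioavailability:
    def test_identity_dose_over_clearance_gives_100_percent(self):
        params = InsulinKineticParams(V_I=15.68, n=0.12)
        dose_U = 22.0
        auc = dose_U * DEFAULT_UNITS.insulin_U_to_pmol / (params.V_I * params.n)
        assert absolute_bioavailability(auc, params, dose_U) == pytest.approx(100.0, rel=1e-12)
        assert absolute_bioavailability(auc / 2, params, dose_U) == pytest.approx(50.0, rel=1e-12)

    def test_bateman_auc_matches_closed_form(self):
        """Dense-grid trapezoid of the absorption profile vs f*Dose/(V_I*n)."""
        params = InsulinKineticParams(V_I=15.68, n=0.12)
        dose_pmol = 22.0 * 6000.0
        f, ka = 0.4, 0.035
        t = np.linspace(0.0, 3000.0, 60001)
        conc = bateman_concentration(t, dose_pmol, f, ka, params)
        auc = np.trapezoid(conc, t)
        assert auc == pytest.approx(f * dose_pmol / (params.V_I * params.n), rel=1e-3)

    def test_pct_exo_scales_inversely_with_dose_unit_factor(self):
        params = InsulinKineticParams(V_I=15.68, n=0.12)
        auc = 3.0e4
        base = absolute_bioavailability(auc, params, 22.0)
        doubled = absolute_bioavailability(
            auc, params, 22.0, units=UnitConversionTable(insulin_U_to_pmol=12000.0)
        )
        assert doubled == pytest.approx(base / 2.0, rel=1e-12)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(DomainError):
            absolute_bioavailability(1e4, InsulinKineticParams(15.0, 0.1), 0.0)
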