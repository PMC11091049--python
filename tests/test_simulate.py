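"""Synthetic cohort generator: determinism, demographic calibration,
absorption kinetics and the suppression mechanism."""

import numpy as np
import pytest

from insep import (
    InsulinKineticParams,
    SimulationConfig,
    bateman_concentration,
    sample_demographics,
    simulate_cohort,
    simulate_meal_test_pair,
    solve_absorption_rate,
    trapezoid_auc,
)
from insep.simulate import _simulate_truth_series


class TestDemographics:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_subjects=10, seed=42)
        a = sample_demographics(cfg)
        b = sample_demographics(cfg)
        assert [(s.age, s.weight, s.bmi, s.sex) for s in a] == [
            (s.age, s.weight, s.bmi, s.sex) for s in b
        ]

    def test_default_cohort_size_matches_study(self):
        assert SimulationConfig().n_subjects == 21

    def test_large_sample_means_match_targets(self):
        cfg = SimulationConfig(n_subjects=1000, seed=5)
        subs = sample_demographics(cfg)
        for attr, (mean, sd, *_rest) in (
            ("age", cfg.demographics["age_y"]),
            ("weight", cfg.demographics["weight_kg"]),
            ("bmi", cfg.demographics["bmi"]),
        ):
            x = np.array([getattr(s, attr) for s in subs])
            se = np.std(x, ddof=1) / np.sqrt(x.size)
            assert abs(np.mean(x) - mean) < 3 * se

    def test_fasting_values_within_population_band(self):
        cfg = SimulationConfig(n_subjects=40, seed=9, noise=False)
        datasets, truths = simulate_cohort(cfg)
        g0 = [ds.glucose.values[0] for ds in datasets if ds.arm == "MT"]
        cp0 = [t.cp_basal for t in truths.values()]
        assert abs(np.mean(g0) - 89.0) < 2 * 6.7
        assert abs(np.mean(cp0) - 1.3 * 331.0) < 2 * 0.6 * 331.0


class TestAbsorption:
    @pytest.mark.parametrize("n", [0.05, 0.0667, 0.12, 0.25])
    def test_peak_time_solved_for_both_branches(self, n):
        ka = solve_absorption_rate(n, 15.0)
        params = InsulinKineticParams(V_I=15.0, n=n)
        t = np.linspace(0.01, 120.0, 12000)
        conc = bateman_concentration(t, 132000.0, 0.4, ka, params)
        assert t[np.argmax(conc)] == pytest.approx(15.0, abs=0.05)

    def test_zero_bioavailable_fraction_gives_zero_profile(self):
        params = InsulinKineticParams(V_I=15.0, n=0.12)
        t = np.linspace(0, 360, 100)
        np.testing.assert_array_equal(
            bateman_concentration(t, 132000.0, 0.0, 0.03, params), 0.0
        )

    def test_profile_nearly_gone_by_240_min(self):
        params = InsulinKineticParams(V_I=15.0, n=0.12)
        ka = solve_absorption_rate(params.n, 15.0)
        t = np.linspace(0, 360, 1000)
        conc = bateman_concentration(t, 132000.0, 0.4, ka, params)
        assert conc[t >= 240].max() < 0.01 * conc.max()

    def test_auc_matches_closed_form(self):
        params = InsulinKineticParams(V_I=15.0, n=0.12)
        ka = solve_absorption_rate(params.n, 15.0)
        t = np.linspace(0, 5000, 200001)
        conc = bateman_concentration(t, 132000.0, 0.4, ka, params)
        expected = 0.4 * 132000.0 / (params.V_I * params.n)
        assert np.trapezoid(conc, t) == pytest.approx(expected, rel=1e-4)


class TestSuppression:
    def test_no_feedback_means_identical_secretion(self):
        cfg = SimulationConfig(
            n_subjects=1, seed=4, noise=False, suppression_strength=0.0,
            bioavailability_sd=0.0,
        )
        subj = sample_demographics(cfg)[0]
        _, _, truth = simulate_meal_test_pair(subj, cfg, subject_seed=7)
        t = np.linspace(0, 360, 200)
        np.testing.assert_allclose(truth.cpsr_mt(t), truth.cpsr_mt_plus_i(t), rtol=1e-12)

    def test_feedback_reduces_supra_basal_secretion(self):
        cfg = SimulationConfig(n_subjects=1, seed=4, noise=False, bioavailability_sd=0.0)
        subj = sample_demographics(cfg)[0]
        _, _, truth = simulate_meal_test_pair(subj, cfg, subject_seed=7)
        t = np.linspace(0, 360, 2000)
        sauc_mt = np.trapezoid(truth.cpsr_mt(t) - truth.basal_sr, t)
        sauc_mti = np.trapezoid(truth.cpsr_mt_plus_i(t) - truth.basal_sr, t)
        assert sauc_mti < sauc_mt

    def test_secretion_returns_to_basal_late(self):
        cfg = SimulationConfig(n_subjects=1, seed=4, noise=False)
        subj = sample_demographics(cfg)[0]
        _, _, truth = simulate_meal_test_pair(subj, cfg, subject_seed=7)
        assert truth.cpsr_mt(5000.0) == pytest.approx(truth.basal_sr, rel=0.02)


class TestPairSimulation:
    def test_no_intervention_makes_arms_identical(self):
        cfg = SimulationConfig(
            n_subjects=1, seed=2, noise=False, suppression_strength=0.0,
            bioavailability_f=0.0, bioavailability_sd=0.0,
        )
        subj = sample_demographics(cfg)[0]
        ds_mt, ds_mti, _ = simulate_meal_test_pair(subj, cfg, subject_seed=3)
        np.testing.assert_array_equal(ds_mt.cpeptide.values, ds_mti.cpeptide.values)
        np.testing.assert_array_equal(ds_mt.insulin.values, ds_mti.insulin.values)

    def test_cohort_deterministic_under_seed(self):
        a, _ = simulate_cohort(SimulationConfig(n_subjects=3, seed=8))
        b, _ = simulate_cohort(SimulationConfig(n_subjects=3, seed=8))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.insulin.values, y.insulin.values)
            np.testing.assert_array_equal(x.cpeptide.values, y.cpeptide.values)

    def test_arms_share_kinetic_truth_and_mti_total_includes_exogenous(self):
        cfg = SimulationConfig(n_subjects=1, seed=6, noise=False, bioavailability_sd=0.0)
        subj = sample_demographics(cfg)[0]
        ds_mt, ds_mti, truth = simulate_meal_test_pair(subj, cfg, subject_seed=9)
        grid = ds_mti.insulin.times
        _, iendo_mti = _simulate_truth_series(
            truth.cp_params, truth.insulin_params, truth.cpsr_mt_plus_i, truth.cp_basal, grid
        )
        np.testing.assert_allclose(
            ds_mti.insulin.values, iendo_mti + truth.iexo(grid), rtol=1e-7
        )

    def test_calibrated_suppression_roughly_halves_endogenous_exposure(self):
        cfg = SimulationConfig(n_subjects=21, seed=0, noise=False)
        _, truths = simulate_cohort(cfg)
        grid = np.asarray(cfg.time_grid)
        ratios = []
        for tr in truths.values():
            _, ie_mt = _simulate_truth_series(tr.cp_params, tr.insulin_params, tr.cpsr_mt, tr.cp_basal, grid)
            _, ie_mti = _simulate_truth_series(tr.cp_params, tr.insulin_params, tr.cpsr_mt_plus_i, tr.cp_basal, grid)
            ratios.append(
                trapezoid_auc(grid, ie_mti, supra_basal=True)
                / trapezoid_auc(grid, ie_mt, supra_basal=True)
            )
        assert 0.3 <= np.mean(ratios) <= 0.7
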