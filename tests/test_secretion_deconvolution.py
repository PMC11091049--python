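"""Piecewise-linear secretion evaluation and Step-1 deconvolution:
exactness on model-matched data, the linear-solve oracle, and noise
behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from insep import (
    DomainError,
    ErrorModel,
    PiecewiseLinearSecretion,
    ValidationError,
    cpeptide_steady_state,
    deconvolve_cpsr,
    evaluate_secretion,
    simulate_cpeptide,
)


@pytest.fixture(scope="module")
def sr():
    return PiecewiseLinearSecretion([0.0, 10.0, 30.0], [100.0, 200.0, 50.0])


class TestEvaluateSecretion:

    def test_breakpoint_returns_node(self, sr):
        assert evaluate_secretion(sr, 10.0) == 200.0

    def test_midpoint_is_mean_of_nodes(self, sr):
        assert evaluate_secretion(sr, 20.0) == pytest.approx(125.0)

    def test_constant_extrapolation_beyond_last(self, sr):
        assert evaluate_secretion(sr, 1000.0) == 50.0

    def test_negative_time_rejected(self, sr):
        with pytest.raises(DomainError):
            evaluate_secretion(sr, -1.0)

    @given(st.floats(min_value=0.0, max_value=30.0))
    @settings(derandomize=True, max_examples=40)
    def test_evaluation_within_node_envelope(self, t):
        sr = PiecewiseLinearSecretion([0.0, 10.0, 30.0], [100.0, 200.0, 50.0])
        v = evaluate_secretion(sr, t)
        assert 50.0 - 1e-9 <= v <= 200.0 + 1e-9

    def test_decreasing_breakpoints_rejected(self):
        with pytest.raises(ValidationError):
            PiecewiseLinearSecretion([0.0, 5.0, 5.0], [1.0, 1.0, 1.0])


def _forward(cp_params, nodes, grid, cp0=None, cp_series_factory=None):
    """Noise-free C-peptide generated from a PWL secretion whose node 0 is
    the basal rate for the fasting concentration implied by steady state."""
    sr = PiecewiseLinearSecretion(grid, nodes)
    cp0_implied = nodes[0] / (cp_params.k01 * cp_params.V_CP1)
    state0, _ = cpeptide_steady_state(cp_params, cp0_implied)
    cp = simulate_cpeptide(cp_params, sr, state0, grid)
    return cp


class TestDeconvolution:
    def test_steady_state_gives_flat_cpsr(self, cp_params, paper_grid, cp_series_factory):
        cp = cp_series_factory(paper_grid, np.full(paper_grid.size, 430.0))
        sr, diag = deconvolve_cpsr(cp, cp_params)
        _, sr0 = cpeptide_steady_state(cp_params, 430.0)
        np.testing.assert_allclose(sr.node_values, sr0, rtol=1e-6)
        assert diag.converged

    def test_triangular_pulse_recovered_exactly(self, cp_params, paper_grid):
        _, sr0 = cpeptide_steady_state(cp_params, 430.0)
        nodes = np.full(paper_grid.size, sr0)
        nodes[2:6] += np.array([150.0, 420.0, 300.0, 80.0])  # pulse over 15-120 min
        cp = _forward(cp_params, nodes, paper_grid)
        sr_hat, diag = deconvolve_cpsr(cp, cp_params)
        np.testing.assert_allclose(sr_hat.node_values, nodes, rtol=1e-6)
        assert diag.converged
        assert np.max(np.abs(diag.studentized_residuals)) < 1e-5

    def test_matches_independent_linear_solve_oracle(
        self, cp_params, paper_grid, cp_oracle, cp_series_factory
    ):
        """Oracle: build the convolution matrix column by column with the
        stiff ODE integrator and solve the square linear system directly."""
        rng = np.random.default_rng(3)
        nodes = rng.uniform(80.0, 600.0, paper_grid.size)
        cp = _forward(cp_params, nodes, paper_grid)

        n = paper_grid.size
        state0, sr0 = cpeptide_steady_state(cp_params, cp.values[0])
        zero = PiecewiseLinearSecretion(paper_grid, np.zeros(n))
        y_free = cp_oracle(cp_params, zero, state0.q1, state0.q2, paper_grid)
        cols = []
        for j in range(n):
            e = np.zeros(n)
            e[j] = 1.0
            basis = PiecewiseLinearSecretion(paper_grid, e)
            cols.append(cp_oracle(cp_params, basis, 0.0, 0.0, paper_grid))
        b = np.column_stack(cols)
        rhs = cp.values[1:] - y_free[1:] - b[1:, 0] * sr0
        oracle_nodes = np.concatenate([[sr0], np.linalg.solve(b[1:, 1:], rhs)])

        sr_hat, _ = deconvolve_cpsr(cp, cp_params)
        np.testing.assert_allclose(sr_hat.node_values, oracle_nodes, rtol=1e-6)
        np.testing.assert_allclose(sr_hat.node_values, nodes, rtol=1e-6)

    def test_nonnegativity_enforced_on_noisy_data(self, cp_params, paper_grid, cp_series_factory):
        rng = np.random.default_rng(0)
        # shallow profile whose unconstrained solution dips negative
        values = 430.0 * np.array([1.0, 0.8, 0.75, 0.7, 0.72, 0.9, 1.0, 0.95, 1.0])
        cp = cp_series_factory(paper_grid, values * rng.lognormal(0.0, 0.08, paper_grid.size))
        sr_hat, _ = deconvolve_cpsr(cp, cp_params)
        assert np.all(sr_hat.node_values >= 0.0)

    def test_scale_equivariance(self, cp_params, paper_grid, cp_series_factory):
        rng = np.random.default_rng(5)
        values = 430.0 * rng.lognormal(0.0, 0.1, paper_grid.size)
        cp1 = cp_series_factory(paper_grid, values)
        cp2 = cp_series_factory(paper_grid, 3.0 * values)
        sr1, _ = deconvolve_cpsr(cp1, cp_params, multistart=0)
        sr2, _ = deconvolve_cpsr(cp2, cp_params, multistart=0)
        np.testing.assert_allclose(sr2.node_values, 3.0 * sr1.node_values, rtol=1e-4)

    def test_too_few_samples_rejected(self, cp_params, cp_series_factory):
        cp = cp_series_factory([0.0, 10.0], [430.0, 430.0])
        with pytest.raises(ValidationError):
            deconvolve_cpsr(cp, cp_params)

    def test_node_error_shrinks_when_noise_halves(self, cp_params, paper_grid):
        """Monte-Carlo: median relative node error under multiplicative noise
        must be finite and decrease when the assay CV halves."""
        _, sr0 = cpeptide_steady_state(cp_params, 430.0)
        nodes = np.full(paper_grid.size, sr0)
        nodes[2:6] += np.array([150.0, 420.0, 300.0, 80.0])
        cp_clean = _forward(cp_params, nodes, paper_grid)
        rng = np.random.default_rng(7)
        medians = {}
        for cv in (0.085, 0.0425):
            errs = []
            for _ in range(80):
                sigma = np.sqrt(np.log(1 + cv**2))
                noisy = cp_clean.values * np.exp(
                    rng.normal(0.0, sigma, paper_grid.size) - sigma**2 / 2
                )
                cp = type(cp_clean)(analyte="cpeptide", times=paper_grid, values=noisy)
                sr_hat, _ = deconvolve_cpsr(cp, cp_params, multistart=0)
                errs.append(np.median(np.abs(sr_hat.node_values - nodes) / nodes))
            medians[cv] = float(np.median(errs))
        assert np.isfinite(medians[0.085])
        assert medians[0.0425] < medians[0.085]

    def test_fixed_cv_error_model_accepted(self, cp_params, paper_grid, cp_series_factory):
        cp = cp_series_factory(paper_grid, np.full(paper_grid.size, 430.0))
        sr, diag = deconvolve_cpsr(cp, cp_params, err=ErrorModel(cv=0.085))
        assert diag.cv_hat == 0.085
        _, sr0 = cpeptide_steady_state(cp_params, 430.0)
        # with a fixed cv the exact ML solution is shrunk slightly below the
        # interpolant by the likelihood's log-prediction normalization term
        # (an O(cv^2) effect), so recovery is approximate, not exact
        np.testing.assert_allclose(sr.node_values, sr0, rtol=0.06)
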