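"""Shared fixtures: reference subject, kinetic parameters, and an
independent stiff-ODE oracle for the two-compartment C-peptide model."""

from __future__ import annotations

import numpy as np
import pytest

from insep import (
    AnalyteSeries,
    SubjectRecord,
    van_cauter_parameters,
)

PAPER_GRID = np.array([0.0, 7.0, 15.0, 30.0, 60.0, 120.0, 240.0, 300.0, 360.0])


@pytest.fixture(scope="session")
def mean_subject() -> SubjectRecord:
    """Cohort-mean demographics of the emulated study."""
    return SubjectRecord(
        subject_id="mean", sex="male", age=28.5, weight=76.8, bmi=26.5, dose_U=22.0
    )


@pytest.fixture(scope="session")
def cp_params(mean_subject):
    return van_cauter_parameters(mean_subject)


@pytest.fixture(scope="session")
def paper_grid() -> np.ndarray:
    return PAPER_GRID.copy()


def ode_cpeptide_oracle(params, secretion, q1_0, q2_0, times, rtol=1e-10):
    """Independent brute-force integration of the two-compartment model with
    scipy's stiff solver; used as the oracle for the analytic propagator."""
    from scipy.integrate import solve_ivp

    def rhs(t, y):
        sr = float(np.asarray(secretion(t)))
        return [
            -(params.k01 + params.k21) * y[0] + params.k12 * y[1] + sr,
            params.k21 * y[0] - params.k12 * y[1],
        ]

    # cap the step so narrow piecewise-linear features (hat basis functions)
    # cannot be stepped over
    max_step = float(np.min(np.diff(times))) / 2.0 if len(times) > 1 else np.inf
    sol = solve_ivp(
        rhs, (0.0, float(times[-1])), [q1_0, q2_0],
        t_eval=times, method="LSODA", rtol=rtol, atol=1e-12, max_step=max_step,
    )
    assert sol.success
    return sol.y[0] / params.V_CP1


@pytest.fixture(scope="session")
def cp_oracle():
    return ode_cpeptide_oracle


def make_cp_series(times, values) -> AnalyteSeries:
    return AnalyteSeries(analyte="cpeptide", times=np.asarray(times, float),
                         values=np.asarray(values, float))


@pytest.fixture(scope="session")
def cp_series_factory():
    return make_cp_series
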