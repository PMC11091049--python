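"""Deconvolution of the C-peptide secretion rate (Step 1).

CPSR(t) is represented as a continuous piecewise-linear function with
breakpoints at the C-peptide sampling times.  The node at t = 0 is fixed at
the basal rate implied by the fasting concentration through the steady
state; the remaining node values (equivalently, the segment slopes) are
estimated by maximum likelihood under a proportional Gaussian error model,
subject to nonnegativity.

Because the two-compartment kinetics are linear, the predicted C-peptide at
the sampling times is affine in the node values, ``CP_pred = d + B s``; the
noise-free problem is square and nonsingular, so model-matched data are
inverted exactly.  The optimizer only has to handle the reweighting induced
by the proportional error model and the nonnegativity bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .cpeptide import CPeptideKineticParams, cpeptide_steady_state
from .datamodel import AnalyteSeries
from .errors import ConvergenceWarning, ValidationError
from .secretion import PiecewiseLinearSecretion


@dataclass
class ErrorModel:
    """Proportional measurement-error model: SD = cv * prediction.

    ``cv=None`` profiles the coefficient of variation out of the likelihood
    (closed form); a fixed value (e.g. the assay CV) can be supplied instead.
    """

    kind: str = "proportional"
    cv: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind != "proportional":
            raise ValidationError(f"unsupported error model {self.kind!r}")
        if self.cv is not None and not self.cv > 0:
            raise ValidationError("fixed cv must be positive")


@dataclass
class FitDiagnostics:
    """Diagnostics of one maximum-likelihood fit."""

    objective: float  # negative log-likelihood (up to an additive constant)
    residuals: np.ndarray  # y - yhat, per sampling time
    studentized_residuals: np.ndarray  # residual / (cv_hat * yhat)
    converged: bool
    n_iter: int
    seed: Optional[int]
    cv_hat: float
    extras: dict = field(default_factory=dict)


def proportional_nll(y: np.ndarray, yhat: np.ndarray, cv: Optional[float]) -> tuple[float, float]:
    """Gaussian negative log-likelihood with SD = cv * yhat.

    Returns ``(nll, cv_used)``; with ``cv=None`` the ML value of cv is
    profiled out in closed form.  Constant terms independent of both the
    parameters and cv are dropped.
    """
    yhat = np.maximum(yhat, 1e-300)
    rel = (y - yhat) / yhat
    m = y.size
    if cv is None:
        cv2 = float(np.mean(rel * rel))
        # floor keeps the profiled likelihood bounded on (near-)perfect fits
        cv2 = max(cv2, 1e-16)
        nll = 0.5 * m * (np.log(cv2) + 1.0) + float(np.sum(np.log(yhat)))
        return nll, float(np.sqrt(cv2))
    nll = 0.5 * float(np.sum(rel * rel)) / cv**2 + float(np.sum(np.log(yhat))) + m * np.log(cv)
    return nll, cv


def _affine_forward_map(
    cp: AnalyteSeries, params: CPeptideKineticParams
) -> tuple[np.ndarray, np.ndarray, float]:
    """Decompose the forward model as CP_pred = y_free + B @ nodes.

    ``y_free`` is the zero-input response from the fasting steady state and
    column j of ``B`` is the response (from an empty system) to the unit hat
    function at breakpoint j.  Returns (y_free, B, sr0).
    """
    from scipy.linalg import expm

    t = cp.times
    n = t.size
    state0, sr0 = cpeptide_steady_state(params, cp.values[0])

    # propagate the free response and all n hat-function responses jointly:
    # augmented state z = [q1, q2, u, v] with u the input value and v its
    # slope, reset at each breakpoint; one matrix exponential per segment
    a_aug = np.zeros((4, 4))
    a_aug[0, 0] = -(params.k01 + params.k21)
    a_aug[0, 1] = params.k12
    a_aug[1, 0] = params.k21
    a_aug[1, 1] = -params.k12
    a_aug[0, 2] = 1.0
    a_aug[2, 3] = 1.0

    nodes = np.eye(n)  # column j = hat function at breakpoint j
    z = np.zeros((4, n + 1))
    z[0, 0], z[1, 0] = state0.q1, state0.q2  # free response, zero input
    b = np.zeros((n, n))
    y_free = np.zeros(n)
    y_free[0] = state0.q1
    for i in range(n - 1):
        dt = t[i + 1] - t[i]
        z[2, 1:] = nodes[i]
        z[3, 1:] = (nodes[i + 1] - nodes[i]) / dt
        z = expm(a_aug * dt) @ z
        y_free[i + 1] = z[0, 0]
        b[i + 1, :] = z[0, 1:]
    return y_free / params.V_CP1, b / params.V_CP1, sr0


def deconvolve_cpsr(
    cp: AnalyteSeries,
    params: CPeptideKineticParams,
    err: Optional[ErrorModel] = None,
    multistart: int = 5,
    seed: int = 0,
    smoothness: float = 0.0,
) -> tuple[PiecewiseLinearSecretion, FitDiagnostics]:
    """Estimate CPSR(t) from sampled C-peptide by maximum likelihood.

    Parameters
    ----------
    cp
        C-peptide series (pmol/L) with at least 3 points and times[0] == 0.
    params
        Subject's two-compartment kinetic parameters.
    err
        Proportional error model; default profiles the CV.
    multistart
        Number of additional jittered restarts beyond the two deterministic
        starts (linear-solve and flat-basal).
    seed
        Seed for the restart jitter.
    smoothness
        Optional penalty weight on squared second differences of the node
        values; 0 (default) reproduces the even-determined construction.
    """
    if err is None:
        err = ErrorModel()
    if cp.times.size < 3:
        raise ValidationError("deconvolution requires at least 3 C-peptide samples")

    t = cp.times
    y = cp.values
    y_free, b, sr0 = _affine_forward_map(cp, params)

    # prediction at the fitted points (t > 0); t = 0 is exact by construction
    base = y_free[1:] + b[1:, 0] * sr0
    g = b[1:, 1:]
    y_fit = y[1:]

    def objective(s: np.ndarray) -> tuple[float, np.ndarray]:
        yhat = np.maximum(base + g @ s, 1e-300)
        nll, _ = proportional_nll(y_fit, yhat, err.cv)
        rel = (y_fit - yhat) / yhat
        m = y_fit.size
        if err.cv is None:
            cv2 = max(float(np.mean(rel * rel)), 1e-16)
            dnll_dyhat = (m / (2.0 * cv2 * m)) * 2.0 * rel * (-y_fit / yhat**2) + 1.0 / yhat
        else:
            dnll_dyhat = rel * (-y_fit / yhat**2) / err.cv**2 + 1.0 / yhat
        grad = g.T @ dnll_dyhat
        if smoothness > 0 and s.size + 1 >= 3:
            nodes = np.concatenate([[sr0], s])
            d2 = np.diff(nodes, n=2)
            nll += smoothness * float(d2 @ d2)
            # gradient of the penalty wrt the free nodes (node 0 fixed)
            gpen = np.zeros(nodes.size)
            for k, v in enumerate(d2):
                gpen[k] += 2 * smoothness * v
                gpen[k + 1] -= 4 * smoothness * v
                gpen[k + 2] += 2 * smoothness * v
            grad = grad + gpen[1:]
        return nll, grad

    rng = np.random.default_rng(seed)
    starts = []
    # unweighted linear solve (exact on noise-free data), clipped to >= 0
    try:
        s_lin = np.linalg.solve(g, y_fit - base)
        starts.append(np.clip(s_lin, 0.0, None))
    except np.linalg.LinAlgError:
        pass
    flat = np.full(t.size - 1, sr0 if sr0 > 0 else max(np.mean(y) * params.k01 * params.V_CP1, 1.0))
    starts.append(flat)
    for _ in range(multistart):
        starts.append(flat * rng.lognormal(0.0, 0.5, size=flat.size))

    best = None
    n_iter = 0
    for s0 in starts:
        res = minimize(
            objective,
            s0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * s0.size,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 2000},
        )
        n_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res

    s_hat = np.clip(best.x, 0.0, None)
    rel_best = (y_fit - (base + g @ s_hat)) / np.maximum(base + g @ s_hat, 1e-300)
    # a numerically perfect fit counts as converged even when the line search
    # stops abnormally on the flat profile-likelihood floor
    converged = bool(best.success) or bool(np.max(np.abs(rel_best)) < 1e-6)
    if not converged:
        warnings.warn(
            f"CPSR deconvolution did not formally converge: {best.message}",
            ConvergenceWarning,
            stacklevel=2,
        )
    nodes = np.concatenate([[sr0], s_hat])
    yhat_full = y_free + b @ nodes
    nll, cv_hat = proportional_nll(y_fit, base + g @ s_hat, err.cv)
    if err.cv is None:
        # profiled cv from the fitted points only (t = 0 has zero residual)
        _, cv_hat = proportional_nll(y_fit, base + g @ s_hat, None)
    residuals = y - yhat_full
    with np.errstate(divide="ignore", invalid="ignore"):
        stud = residuals / (cv_hat * np.maximum(yhat_full, 1e-300))
    diag = FitDiagnostics(
        objective=float(best.fun),
        residuals=residuals,
        studentized_residuals=stud,
        converged=converged,
        n_iter=int(n_iter),
        seed=seed,
        cv_hat=float(cv_hat),
        extras={"sr0": float(sr0), "n_starts": len(starts)},
    )
    return PiecewiseLinearSecretion(t, nodes), diag
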