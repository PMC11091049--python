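"""Two-compartment C-peptide kinetics with population parameters.

Model
-----
C-peptide distributes in an accessible compartment (amount ``q1``, volume
``V_CP1``) exchanging with a peripheral compartment (``q2``) and eliminated
irreversibly from the accessible one::

    dq1/dt = -(k01 + k21) q1 + k12 q2 + SR(t)
    dq2/dt =   k21 q1 - k12 q2
    CP(t)  =   q1 / V_CP1

``k21`` is the accessible-to-peripheral transfer rate, ``k12`` the return
transfer and ``k01`` the elimination rate (all min^-1).  NOTE: both index
conventions circulate in the literature; this package fixes the one above
because it reproduces the published population value set from the
biexponential constants.

The population method assigns the parameters from demographics: the impulse
response is ``F exp(-a t) + (1-F) exp(-b t)`` with ``a = ln2 / t_short``,
``b = ln2 / t_long(age)``; then ``k12 = F b + (1-F) a``, ``k01 = a b / k12``
and ``k21 = a + b - k12 - k01``; ``V_CP1`` is linear in body surface area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from scipy.linalg import expm

from .constants import get_constants
from .datamodel import AnalyteSeries, SubjectRecord, derive_height
from .errors import DomainError, ValidationError
from .secretion import PiecewiseLinearSecretion


@dataclass(frozen=True)
class BiexponentialImpulse:
    """Normalized biexponential impulse response F e^{-at'} + (1-F) e^{-bt'}
    expressed through half-lives (min) and the fast fraction F."""

    half_life_short: float
    half_life_long: float
    fraction_short: float

    def __post_init__(self) -> None:
        if not (0 < self.half_life_short < self.half_life_long):
            raise ValidationError("require 0 < half_life_short < half_life_long")
        if not (0 < self.fraction_short < 1):
            raise ValidationError("fraction_short must lie in (0, 1)")

    @property
    def a(self) -> float:
        """Fast exponent, min^-1."""
        return math.log(2.0) / self.half_life_short

    @property
    def b(self) -> float:
        """Slow exponent, min^-1."""
        return math.log(2.0) / self.half_life_long


@dataclass(frozen=True)
class CPeptideKineticParams:
    """Micro-constants of the two-compartment C-peptide model."""

    V_CP1: float  # L
    k12: float  # min^-1, peripheral -> accessible (return)
    k21: float  # min^-1, accessible -> peripheral
    k01: float  # min^-1, irreversible elimination from accessible

    def __post_init__(self) -> None:
        for name in ("V_CP1", "k12", "k21", "k01"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")
        a, b = self.exponents()
        if not (a > 0 and b > 0 and a != b):
            raise ValidationError("implied exponents must be real, distinct and positive")

    def exponents(self) -> tuple:
        """(a, b) with a > b: decay exponents of the impulse response,
        roots of s^2 - (k01+k21+k12)s + k01*k12 (sign convention s = -root)."""
        s = self.k01 + self.k21 + self.k12
        p = self.k01 * self.k12
        disc = s * s - 4.0 * p
        if disc < 0:
            raise ValidationError("complex exponents: invalid rate-constant combination")
        r = math.sqrt(disc)
        return (s + r) / 2.0, (s - r) / 2.0

    def impulse(self) -> BiexponentialImpulse:
        """The biexponential impulse response implied by the micro-constants."""
        a, b = self.exponents()
        # fraction F solves k12 = F b + (1-F) a
        f = (self.k12 - a) / (b - a)
        return BiexponentialImpulse(
            half_life_short=math.log(2.0) / a,
            half_life_long=math.log(2.0) / b,
            fraction_short=f,
        )


@dataclass
class CPeptideState:
    """Compartment amounts (pmol)."""

    q1: float
    q2: float

    def __post_init__(self) -> None:
        if self.q1 < 0 or self.q2 < 0:
            raise DomainError("compartment amounts must be nonnegative")


def body_surface_area(weight: float, height: float) -> float:
    """DuBois body surface area (m^2): 0.007184 W^0.425 (100 H)^0.725
    with weight in kg and height in m."""
    if not (weight > 0 and height > 0):
        raise DomainError("weight and height must be positive")
    return 0.007184 * weight**0.425 * (100.0 * height) ** 0.725


def params_from_impulse(imp: BiexponentialImpulse, V_CP1: float) -> CPeptideKineticParams:
    """Micro-constants from the population biexponential and a volume."""
    a, b, f = imp.a, imp.b, imp.fraction_short
    k12 = f * b + (1.0 - f) * a
    k01 = a * b / k12
    k21 = a + b - k12 - k01
    return CPeptideKineticParams(V_CP1=V_CP1, k12=k12, k21=k21, k01=k01)


def van_cauter_parameters(
    subject: SubjectRecord, constants: Optional[dict] = None
) -> CPeptideKineticParams:
    """Population C-peptide kinetic parameters from demographics.

    Uses the subject's category to pick the population constant set (only
    ``"normal"`` ships), the age-dependent long half-life and the
    BSA-regression distribution volume.
    """
    consts = constants if constants is not None else get_constants(subject.category)
    imp = BiexponentialImpulse(
        half_life_short=consts["short_half_life_min"],
        half_life_long=consts["long_half_life_intercept_min"]
        + consts["long_half_life_age_slope_min_per_y"] * subject.age,
        fraction_short=consts["fraction_short"],
    )
    bsa = body_surface_area(subject.weight, derive_height(subject))
    v1 = consts["volume_intercept_L"] + consts["volume_slope_L_per_m2"] * bsa
    return params_from_impulse(imp, V_CP1=v1)


def cpeptide_steady_state(
    params: CPeptideKineticParams, cp0: float
) -> tuple[CPeptideState, float]:
    """Steady state consistent with a fasting concentration ``cp0`` (pmol/L).

    Returns the compartment amounts and the constant basal secretion rate
    ``sr0 = k01 V_CP1 cp0`` (pmol/min) that holds the system there.
    """
    if cp0 < 0:
        raise DomainError("cp0 must be nonnegative")
    q1 = params.V_CP1 * cp0
    q2 = (params.k21 / params.k12) * q1
    sr0 = params.k01 * q1
    return CPeptideState(q1=q1, q2=q2), sr0


def _system_matrix(params: CPeptideKineticParams) -> np.ndarray:
    return np.array(
        [
            [-(params.k01 + params.k21), params.k12],
            [params.k21, -params.k12],
        ]
    )


def simulate_cpeptide(
    params: CPeptideKineticParams,
    secretion: Union[PiecewiseLinearSecretion, Callable[[float], float]],
    state0: CPeptideState,
    times: np.ndarray,
) -> AnalyteSeries:
    """Forward-simulate plasma C-peptide for a given secretion input.

    For a piecewise-linear input the solution is exact: the 2x2 linear system
    is augmented with the input value and slope and propagated with a matrix
    exponential per segment.  For a general callable input an adaptive stiff
    integrator (LSODA, rtol 1e-10) is used.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValidationError("times must be a nonempty strictly increasing grid with times[0] >= 0")

    if isinstance(secretion, PiecewiseLinearSecretion):
        q1 = _propagate_pwl(params, secretion, state0, times)
    else:
        q1 = _propagate_callable(params, secretion, state0, times)
    return AnalyteSeries(analyte="cpeptide", times=times, values=q1 / params.V_CP1,
                         source_unit="pmol/L")


def _propagate_pwl(params, sr: PiecewiseLinearSecretion, state0, times) -> np.ndarray:
    m = _system_matrix(params)
    # augmented state z = [q1, q2, u, v]: du/dt = v, dv/dt = 0; u(t) = SR(t)
    a_aug = np.zeros((4, 4))
    a_aug[:2, :2] = m
    a_aug[0, 2] = 1.0
    a_aug[2, 3] = 1.0

    grid = np.unique(np.concatenate([times, sr.breakpoints, [0.0]]))
    grid = grid[(grid >= 0) & (grid <= times[-1])]

    cache: dict = {}
    z = np.array([state0.q1, state0.q2, 0.0, 0.0])
    out = {}
    t_prev = grid[0]
    if t_prev in times:
        out[t_prev] = z[0]
    for t_next in grid[1:]:
        dt = t_next - t_prev
        u0 = float(sr(t_prev))
        u1 = float(sr(t_next))
        # within a segment the input is linear; beyond the last breakpoint
        # it is constant, so the slope below is 0 there
        slope = (u1 - u0) / dt
        z[2], z[3] = u0, slope
        key = round(dt, 12)
        if key not in cache:
            cache[key] = expm(a_aug * dt)
        z = cache[key] @ z
        if t_next in times:
            out[t_next] = z[0]
        t_prev = t_next
    return np.array([out[t] for t in times])


def _propagate_callable(params, secretion, state0, times) -> np.ndarray:
    from scipy.integrate import solve_ivp

    m = _system_matrix(params)

    def rhs(t, y):
        sr = float(secretion(t))
        return m @ y + np.array([sr, 0.0])

    t_eval = times if times[0] == 0 else np.concatenate([[0.0], times])
    sol = solve_ivp(
        rhs, (0.0, float(times[-1])), [state0.q1, state0.q2],
        t_eval=t_eval, method="LSODA", rtol=1e-10, atol=1e-10,
    )
    if not sol.success:
        raise DomainError(f"C-peptide integration failed: {sol.message}")
    q1 = sol.y[0]
    return q1 if times[0] == 0 else q1[1:]
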