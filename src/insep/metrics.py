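"""Step 3 and summary metrics: exogenous decomposition, AUCs, the
insulin-to-C-peptide fractional temporal ratio (ICPR) and absolute
bioavailability.

The exogenous component is obtained by subtraction,
``Iexo(t_i) = I_total(t_i) - Iendo(t_i)``; negative values (model misfit or
noise) are retained, not clipped, and counted in a diagnostic, because
clipping would bias the exogenous exposure upward.

Absolute bioavailability compares the exogenous AUC with the AUC an
intravenous bolus of the same dose would produce under the fitted
one-compartment kinetics, ``AUC_IV = Dose / (V_I * n)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datamodel import AnalyteSeries
from .errors import DomainError, ValidationError
from .insulin import EndogenousPrediction, InsulinKineticParams
from .units import DEFAULT_UNITS, UnitConversionTable


@dataclass
class DecompositionResult:
    """Per-subject decomposition of total plasma insulin (inhaled-insulin arm)."""

    times: np.ndarray  # min
    i_total: np.ndarray  # measured total insulin, pmol/L
    i_endo: np.ndarray  # predicted endogenous component, pmol/L
    i_exo: np.ndarray  # difference; may be slightly negative
    n_negative_iexo: int = 0
    icpr_t: Optional[np.ndarray] = None  # dimensionless, per time
    auc_iexo: Optional[float] = None  # pmol*min/L
    sauc_iendo: Optional[float] = None  # pmol*min/L
    pct_exo_of_total: Optional[float] = None  # %
    pct_bioavailability: Optional[float] = None  # %
    extras: dict = field(default_factory=dict)


def subtract_exogenous(
    i_total: AnalyteSeries, i_endo: EndogenousPrediction
) -> DecompositionResult:
    """Step 3: exogenous component by subtraction on the shared grid."""
    if i_total.times.shape != i_endo.times.shape or not np.allclose(
        i_total.times, i_endo.times, rtol=0, atol=1e-9
    ):
        raise ValidationError("i_total and i_endo must share one time grid")
    i_exo = i_total.values - i_endo.iendo
    return DecompositionResult(
        times=i_total.times.copy(),
        i_total=i_total.values.copy(),
        i_endo=i_endo.iendo.copy(),
        i_exo=i_exo,
        n_negative_iexo=int(np.sum(i_exo < 0)),
    )


def trapezoid_auc(
    times: np.ndarray,
    values: np.ndarray,
    t_start: Optional[float] = None,
    t_end: Optional[float] = None,
    baseline: float = 0.0,
    supra_basal: bool = False,
    truncate_negative: bool = False,
) -> float:
    """Trapezoidal area under (values - baseline) on [t_start, t_end].

    ``supra_basal=True`` uses the value at t = 0 as the baseline (the usual
    sAUC convention); negative increments are included unless
    ``truncate_negative`` is set.  Interval endpoints inside the grid are
    handled by linear interpolation.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if t_start is None:
        t_start = float(times[0])
    if t_end is None:
        t_end = float(times[-1])
    if not t_end > t_start:
        raise DomainError("t_end must exceed t_start")
    if t_start < times[0] or t_end > times[-1]:
        raise DomainError("integration interval must lie within the sampled span")
    if supra_basal:
        baseline = float(np.interp(0.0, times, values)) if times[0] <= 0.0 else float(values[0])

    inner = (times > t_start) & (times < t_end)
    tt = np.concatenate([[t_start], times[inner], [t_end]])
    vv = np.interp(tt, times, values) - baseline
    if truncate_negative:
        vv = np.clip(vv, 0.0, None)
    return float(np.trapezoid(vv, tt))


def icpr_profile(i_endo: EndogenousPrediction, cp: AnalyteSeries) -> np.ndarray:
    """Time-varying insulin-to-C-peptide fractional ratio
    ICPR(t_i) = Iendo(t_i) / CP(t_i); NaN (with a warning) where CP = 0."""
    if i_endo.times.shape != cp.times.shape or not np.allclose(
        i_endo.times, cp.times, rtol=0, atol=1e-9
    ):
        raise ValidationError("i_endo and cp must share one time grid")
    out = np.full(cp.values.shape, np.nan)
    ok = cp.values > 0
    out[ok] = i_endo.iendo[ok] / cp.values[ok]
    if not ok.all():
        warnings.warn(
            f"ICPR undefined at {int((~ok).sum())} time point(s) with zero C-peptide",
            stacklevel=2,
        )
    return out


def absolute_bioavailability(
    auc_iexo: float,
    params: InsulinKineticParams,
    dose_U: float,
    units: UnitConversionTable = DEFAULT_UNITS,
) -> float:
    """Absolute bioavailability (%): 100 * AUC_Iexo / AUC_IV with
    AUC_IV = Dose / (V_I * n) for an intravenous bolus of the same dose."""
    if not dose_U > 0:
        raise DomainError("dose_U must be positive")
    dose_pmol = dose_U * units.insulin_U_to_pmol
    auc_iv = dose_pmol / (params.V_I * params.n)
    return 100.0 * auc_iexo / auc_iv


def decompose(
    i_total: AnalyteSeries,
    i_endo: EndogenousPrediction,
    cp: AnalyteSeries,
    params: InsulinKineticParams,
    dose_U: float,
    units: UnitConversionTable = DEFAULT_UNITS,
    auc_interval: tuple = (0.0, None),
) -> DecompositionResult:
    """Full Step-3 decomposition with summary metrics for one subject's
    inhaled-insulin arm."""
    result = subtract_exogenous(i_total, i_endo)
    t0, t1 = auc_interval
    result.icpr_t = icpr_profile(i_endo, cp)
    result.auc_iexo = trapezoid_auc(result.times, result.i_exo, t_start=t0, t_end=t1)
    result.sauc_iendo = trapezoid_auc(result.times, result.i_endo, supra_basal=True)
    auc_total = trapezoid_auc(result.times, result.i_total, t_start=t0, t_end=t1)
    result.pct_exo_of_total = 100.0 * result.auc_iexo / auc_total if auc_total > 0 else np.nan
    result.pct_bioavailability = absolute_bioavailability(
        result.auc_iexo, params, dose_U, units
    )
    return result
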