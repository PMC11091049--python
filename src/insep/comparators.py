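"""Comparator C-peptide correction methods.

Both comparators assume a time-constant proportionality between endogenous
insulin and C-peptide during the test:

* Baseline (Owens) correction: the ratio is fixed by the fasting samples,
  ICPR = I(0)/CP(0), and Iendo(t) = ICPR * CP(t).
* Linear-mixed-effects (Marino) correction: I(t) = (Slope + v_subject) *
  CP(t) + Intercept + error, with a fixed intercept, a fixed mean slope and
  a per-subject random slope; fitted on the cohort's plain meal-test arms
  and then applied to the inhaled-insulin arms.

In contrast with the dynamic three-step method, both produce a per-subject
ICPR that does not vary over the test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd

from .datamodel import AnalyteSeries, MealTestDataset
from .errors import DomainError, EstimationError, ValidationError


def _check_shared_grid(i: AnalyteSeries, cp: AnalyteSeries) -> None:
    if i.times.shape != cp.times.shape or not np.allclose(i.times, cp.times, rtol=0, atol=1e-9):
        raise ValidationError("insulin and C-peptide series must share one time grid")


def owens_baseline_correction(
    i: AnalyteSeries, cp: AnalyteSeries
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Baseline correction: returns (icpr, i_endo, i_exo) with
    icpr = I(0)/CP(0), i_endo = icpr * CP(t), i_exo = I(t) - i_endo(t)."""
    _check_shared_grid(i, cp)
    if not cp.values[0] > 0:
        raise DomainError("fasting C-peptide must be positive for baseline correction")
    icpr = float(i.values[0] / cp.values[0])
    i_endo = icpr * cp.values
    i_exo = i.values - i_endo
    return icpr, i_endo, i_exo


@dataclass
class LmeCorrectionModel:
    """Fitted linear-mixed-effects correction: fixed slope and intercept plus
    per-subject random slope deviations."""

    slope: float  # dimensionless fixed-effect mean
    intercept: float  # pmol/L fixed effect
    v_subject: Dict[str, float]  # per-subject slope deviation
    residual_sd: float  # pmol/L
    slope_re_sd: float = np.nan  # SD of the random slope
    converged: bool = True
    extras: dict = field(default_factory=dict)


def fit_marino_lme(cohort_mt: Iterable[MealTestDataset]) -> LmeCorrectionModel:
    """Fit I = (Slope + v_subject) * CP + Intercept + error on the cohort's
    plain meal-test arms by maximum likelihood (random slope, no random
    intercept), pooling all time points with equal weight."""
    import statsmodels.api as sm

    rows = []
    for ds in cohort_mt:
        if ds.arm != "MT":
            continue
        _check_shared_grid(ds.insulin, ds.cpeptide)
        for t, ins, cp in zip(ds.insulin.times, ds.insulin.values, ds.cpeptide.values):
            rows.append({"subject": ds.subject.subject_id, "I": ins, "CP": cp})
    df = pd.DataFrame(rows)
    if df.empty or df["subject"].nunique() < 2:
        raise EstimationError(
            "the mixed-effects correction needs plain meal-test data from at "
            "least 2 subjects (random-slope variance is not estimable otherwise)"
        )

    exog = sm.add_constant(df[["CP"]])
    model = sm.MixedLM(
        endog=df["I"].to_numpy(),
        exog=exog.to_numpy(),
        groups=df["subject"].to_numpy(),
        exog_re=df[["CP"]].to_numpy(),
    )
    import warnings as _warnings

    # the gradient optimizer can collapse the random-slope variance to a
    # degenerate local optimum; race it against a direct-search fit and keep
    # the higher likelihood
    fits = []
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # near-zero variances on clean data
        for method in ("lbfgs", "powell"):
            try:
                fits.append(model.fit(reml=False, method=method, maxiter=500))
            except Exception:
                continue
    if not fits:
        raise EstimationError("mixed-effects fit failed with all optimizers")
    finite = [f for f in fits if np.isfinite(f.llf)]
    fit = max(finite or fits, key=lambda f: f.llf)

    intercept, slope = fit.fe_params
    subjects = df["subject"].unique()
    try:
        v = {str(k): float(np.asarray(re).ravel()[0]) for k, re in fit.random_effects.items()}
    except ValueError:
        # random-slope variance estimated at zero: no predictable subject
        # deviations, the correction collapses to the fixed effects
        v = {str(k): 0.0 for k in subjects}
    return LmeCorrectionModel(
        slope=float(slope),
        intercept=float(intercept),
        v_subject=v,
        residual_sd=float(np.sqrt(fit.scale)),
        slope_re_sd=float(np.sqrt(max(np.asarray(fit.cov_re).ravel()[0], 0.0))),
        converged=bool(fit.converged),
        extras={"n_obs": int(df.shape[0]), "n_subjects": int(df["subject"].nunique())},
    )


def apply_marino_correction(
    model: LmeCorrectionModel,
    subject_id: str,
    i: AnalyteSeries,
    cp: AnalyteSeries,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Apply the fitted correction to one subject's series: returns
    (icpr, i_endo, i_exo) with icpr = Slope + v_subject and
    i_endo = icpr * CP(t) + Intercept."""
    _check_shared_grid(i, cp)
    if subject_id not in model.v_subject:
        raise KeyError(f"subject {subject_id!r} was not part of the mixed-effects fit")
    icpr = model.slope + model.v_subject[subject_id]
    i_endo = icpr * cp.values + model.intercept
    i_exo = i.values - i_endo
    return float(icpr), i_endo, i_exo
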