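"""Synthetic paired meal-test cohorts with known ground truth.

The generator emulates the study design the pipeline targets: 21 healthy
adults, two meal-test arms per subject (with and without a prior inhaled
insulin dose), 9 samples at 0, 7, 15, 30, 60, 120, 240, 300, 360 min, and
multiplicative assay noise (insulin CV 4.5%, C-peptide CV 8.5%).

Ground truth per subject:

* C-peptide kinetics from the population (Van Cauter) method — the same
  parameters the analysis will assume, so Step 1 kinetics carry no
  population/individual mismatch (a deliberate simplification; see docs).
* True secretion CPSR(t) = basal + gamma-variate meal burst.  The burst is a
  smooth curve deliberately outside the piecewise-linear model class;
  ``pwl_truth=True`` switches to a model-matched piecewise-linear truth for
  exactness tests.
* One-compartment insulin kinetics (V_I, n) shared by both arms.
* Inhaled dose: first-order (Bateman) absorption of the bioavailable
  fraction, with the absorption rate solved so the exogenous concentration
  peaks near 15 min; the exogenous insulin feeds back on secretion in the
  MT_I arm through a saturating suppression factor.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .cpeptide import CPeptideKineticParams, cpeptide_steady_state, van_cauter_parameters
from .datamodel import ARM_MT, ARM_MT_I, STUDY_TIME_GRID, AnalyteSeries, MealTestDataset, SubjectRecord
from .errors import DomainError, ValidationError
from .insulin import InsulinKineticParams
from .units import DEFAULT_UNITS

#: Exogenous insulin concentration (pmol/L) at which secretion suppression
#: reaches half of its asymptotic strength.
SUPPRESSION_REF_PMOL_PER_L = 100.0


@dataclass
class SimulationConfig:
    """Study-design and truth parameters of the synthetic cohort.

    Defaults reproduce the emulated study: cohort size, sampling grid, assay
    CVs, dose, and demographic means/SDs.  ``suppression_strength`` is
    calibrated so the inhaled-insulin arm's supra-basal endogenous insulin
    exposure is roughly half of the plain arm's (the qualitative cohort
    pattern the real study reports); ``bioavailability_f`` matches the
    reported mean absolute bioavailability of 42%.
    """

    n_subjects: int = 21
    seed: int = 0
    time_grid: tuple = STUDY_TIME_GRID
    insulin_cv: float = 0.045
    cpeptide_cv: float = 0.085
    dose_U: float = 22.0
    bioavailability_f: float = 0.42
    bioavailability_sd: float = 0.21
    absorption_peak_min: float = 15.0
    suppression_strength: float = 8.0
    noise: bool = True
    pwl_truth: bool = False
    # demographics: (mean, sd, low, high) for mean-matched truncated normals
    demographics: dict = field(default_factory=lambda: {
        "age_y": (28.5, 8.6, 18.0, 55.0),
        "weight_kg": (76.8, 13.5, 45.0, 120.0),
        "bmi": (26.5, 3.0, 18.5, 35.0),
        "glucose_b_mg_dl": (89.0, 6.7, 65.0, 110.0),
        "cpeptide_b_pmol_l": (1.3 * 331.0, 0.6 * 331.0, 150.0, 900.0),
    })
    # insulin kinetic truth: (mean, sd, low, high)
    vi_L: tuple = (15.68, 5.74, 6.0, 35.0)
    n_per_min: tuple = (0.12, 0.05, 0.05, 0.30)
    # biphasic meal secretion: early burst peaking at U(40, 80) min plus a
    # sustained second phase (stretched, flatter gamma-variate), total
    # amplitude U(3, 6) x basal at the early peak
    meal_peak_min: tuple = (40.0, 80.0)
    meal_amplitude_x_basal: tuple = (3.0, 6.0)
    meal_shape: float = 2.0
    meal_second_phase_fraction: float = 0.5
    meal_second_phase_stretch: float = 2.5
    meal_second_phase_shape: float = 1.2

    def __post_init__(self) -> None:
        grid = np.asarray(self.time_grid, dtype=float)
        if grid[0] != 0 or np.any(np.diff(grid) <= 0):
            raise ValidationError("time_grid must start at 0 and be strictly increasing")
        for cv in (self.insulin_cv, self.cpeptide_cv):
            if not (0 < cv < 0.5):
                raise ValidationError("assay CVs must lie in (0, 0.5)")
        if not (0 <= self.bioavailability_f <= 1):
            raise ValidationError("bioavailability_f must lie in [0, 1]")
        if self.suppression_strength < 0:
            raise DomainError("suppression_strength must be nonnegative")


@dataclass
class TruthRecord:
    """Ground truth of one simulated subject (shared by both arms)."""

    cp_params: CPeptideKineticParams
    insulin_params: InsulinKineticParams
    cpsr_mt: Callable[[float], float]
    cpsr_mt_plus_i: Callable[[float], float]
    iexo: Callable[[float], float]  # exogenous concentration, pmol/L
    pct_bioavailability: float  # 100 * absorbed fraction
    bioavailability_f: float
    absorption_ka: float  # min^-1
    basal_sr: float  # pmol/min
    cp_basal: float  # pmol/L
    meal_peak_min: float
    meal_amplitude: float  # pmol/min above basal at the burst peak
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "V_CP1": self.cp_params.V_CP1, "k12": self.cp_params.k12,
            "k21": self.cp_params.k21, "k01": self.cp_params.k01,
            "V_I": self.insulin_params.V_I, "n": self.insulin_params.n,
            "pct_bioavailability": self.pct_bioavailability,
            "bioavailability_f": self.bioavailability_f,
            "absorption_ka": self.absorption_ka,
            "basal_sr": self.basal_sr, "cp_basal": self.cp_basal,
            "meal_peak_min": self.meal_peak_min, "meal_amplitude": self.meal_amplitude,
            "seed": self.seed,
        }


def _mean_matched_truncnorm(rng, mean, sd, low, high, size):
    """Truncated normal whose truncated mean equals ``mean`` (the location of
    the parent normal is shifted to compensate for the truncation)."""
    def trunc_mean(mu):
        a, b = (low - mu) / sd, (high - mu) / sd
        return truncnorm.mean(a, b, loc=mu, scale=sd)

    lo_mu, hi_mu = low - 5 * sd, high + 5 * sd
    mu = brentq(lambda m: trunc_mean(m) - mean, lo_mu, hi_mu, xtol=1e-10)
    a, b = (low - mu) / sd, (high - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def sample_demographics(cfg: SimulationConfig) -> List[SubjectRecord]:
    """Draw a cohort of subject records matching the emulated study's
    demographic means and SDs; deterministic under ``cfg.seed``."""
    if cfg.n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    age = _mean_matched_truncnorm(rng, *cfg.demographics["age_y"], size=n)
    weight = _mean_matched_truncnorm(rng, *cfg.demographics["weight_kg"], size=n)
    bmi = _mean_matched_truncnorm(rng, *cfg.demographics["bmi"], size=n)
    sex = rng.random(n) < 0.5
    return [
        SubjectRecord(
            subject_id=f"S{i + 1:03d}",
            sex="male" if sex[i] else "female",
            age=float(age[i]),
            weight=float(weight[i]),
            bmi=float(bmi[i]),
            dose_U=cfg.dose_U,
        )
        for i in range(n)
    ]


def _gamma_variate(t, peak_time, shape):
    """Normalized gamma-variate burst: 0 at t=0, 1 at t=peak_time."""
    t = np.asarray(t, dtype=float)
    x = np.clip(t / peak_time, 0.0, None)
    return x**shape * np.exp(shape * (1.0 - x))


def solve_absorption_rate(n: float, t_peak: float) -> float:
    """Absorption rate constant ka of a Bateman profile peaking at ``t_peak``
    given elimination rate ``n``: solves ln(ka/n)/(ka - n) = t_peak.

    When 1/n > t_peak absorption must be faster than elimination (ka > n);
    when 1/n < t_peak the solution is flip-flop kinetics (ka < n).
    """
    if not (n > 0 and t_peak > 0):
        raise DomainError("n and t_peak must be positive")
    if abs(1.0 / n - t_peak) < 1e-9:
        return n  # degenerate ka == n: peak at exactly 1/n

    def g(ka):
        return math.log(ka / n) - t_peak * (ka - n)

    # g has roots at ka = n (trivial) and at the Bateman solution on the
    # other side of its maximum at ka = 1/t_peak
    kam = 1.0 / t_peak
    if n < kam:  # solution above the maximum
        hi = kam
        while g(hi) > 0:
            hi *= 2.0
        return brentq(g, kam, hi, xtol=1e-12)
    lo = kam * 1e-8
    while g(lo) > 0:
        lo *= 0.1
    return brentq(g, lo, kam, xtol=1e-12)


def bateman_concentration(
    t, dose_pmol: float, f: float, ka: float, params: InsulinKineticParams
):
    """Exogenous insulin concentration (pmol/L) after first-order absorption
    of the bioavailable fraction ``f`` of a dose given at t = 0."""
    t = np.asarray(t, dtype=float)
    n, v = params.n, params.V_I
    amount = f * dose_pmol
    if abs(ka - n) < 1e-12:
        out = amount * n * t * np.exp(-n * t) / v
    else:
        out = amount * ka / (v * (ka - n)) * (np.exp(-n * t) - np.exp(-ka * t))
    return np.where(t >= 0, out, 0.0)


def exogenous_pk_profile(
    subject: SubjectRecord,
    dose_U: float,
    cfg: SimulationConfig,
    insulin_params: InsulinKineticParams,
    f: float,
) -> Tuple[Callable, float]:
    """Continuous exogenous insulin concentration function and the solved
    absorption rate ka for one subject."""
    if not dose_U > 0:
        raise DomainError("dose_U must be positive")
    ka = solve_absorption_rate(insulin_params.n, cfg.absorption_peak_min)
    dose_pmol = dose_U * DEFAULT_UNITS.insulin_U_to_pmol

    def profile(t):
        return bateman_concentration(t, dose_pmol, f, ka, insulin_params)

    return profile, ka


def true_secretion(
    basal_sr: float,
    meal_amplitude: float,
    peak_time: float,
    shape: float,
    cfg: SimulationConfig,
    exo_profile: Optional[Callable] = None,
) -> Callable:
    """Continuous true CPSR(t): basal plus a biphasic meal response,
    multiplied by the exogenous-insulin suppression factor in the inhaled arm.

    The meal response mixes an early gamma-variate burst (peaking at
    ``peak_time``) with a flatter, stretched second phase that keeps
    secretion above basal through the late test, as observed in 6-h meal
    tests.  The suppression emulates the negative insulin feedback on
    secretion: suppression(t) = 1 / (1 + strength * Iexo(t) / I_ref).  With
    ``exo_profile=None`` (plain meal-test arm) suppression is identically 1.
    """
    if basal_sr < 0 or meal_amplitude < 0:
        raise DomainError("basal_sr and meal_amplitude must be nonnegative")
    w2 = cfg.meal_second_phase_fraction

    def cpsr(t):
        t = np.asarray(t, dtype=float)
        early = _gamma_variate(t, peak_time, shape)
        late = _gamma_variate(
            t, cfg.meal_second_phase_stretch * peak_time, cfg.meal_second_phase_shape
        )
        meal = meal_amplitude * ((1.0 - w2) * early + w2 * late)
        if exo_profile is not None and cfg.suppression_strength > 0:
            supp = 1.0 / (
                1.0 + cfg.suppression_strength * np.asarray(exo_profile(t)) / SUPPRESSION_REF_PMOL_PER_L
            )
        else:
            supp = 1.0
        return basal_sr + meal * supp

    return cpsr


def _simulate_truth_series(
    cp_params: CPeptideKineticParams,
    ins_params: InsulinKineticParams,
    cpsr: Callable,
    cp_basal: float,
    times: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Joint high-accuracy integration of C-peptide (2 compartments) and the
    endogenous insulin amount; returns (CP(t), Iendo(t)) at ``times``."""
    state0, sr0 = cpeptide_steady_state(cp_params, cp_basal)
    a0 = float(cpsr(0.0)) / ins_params.n

    k01, k21, k12 = cp_params.k01, cp_params.k21, cp_params.k12

    def rhs(t, y):
        q1, q2, a = y
        sr = float(cpsr(t))
        return [
            -(k01 + k21) * q1 + k12 * q2 + sr,
            k21 * q1 - k12 * q2,
            -ins_params.n * a + sr,
        ]

    sol = solve_ivp(
        rhs, (0.0, float(times[-1])), [state0.q1, state0.q2, a0],
        t_eval=times, method="LSODA", rtol=1e-9, atol=1e-9,
    )
    if not sol.success:
        raise RuntimeError(f"truth integration failed: {sol.message}")
    return sol.y[0] / cp_params.V_CP1, sol.y[2] / ins_params.V_I


def _lognormal_noise(rng, values: np.ndarray, cv: float) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return values * np.exp(rng.normal(0.0, sigma, size=values.shape) - 0.5 * sigma**2)


def simulate_meal_test_pair(
    subject: SubjectRecord,
    cfg: SimulationConfig,
    subject_seed: Optional[int] = None,
) -> Tuple[MealTestDataset, MealTestDataset, TruthRecord]:
    """Simulate one subject's paired arms plus the ground truth.

    ``subject_seed`` isolates the subject's random draws; by default it is
    derived from ``cfg.seed`` and the subject id, so cohorts are reproducible
    and subjects are independent.
    """
    if subject_seed is None:
        sid_hash = zlib.crc32(subject.subject_id.encode())  # stable across runs
        subject_seed = int(
            np.random.SeedSequence([cfg.seed, sid_hash]).generate_state(1)[0] % (2**31)
        )
    rng = np.random.default_rng(subject_seed)
    times = np.asarray(cfg.time_grid, dtype=float)

    cp_params = van_cauter_parameters(subject)
    vi = float(_mean_matched_truncnorm(rng, *cfg.vi_L, size=1)[0])
    n = float(_mean_matched_truncnorm(rng, *cfg.n_per_min, size=1)[0])
    ins_params = InsulinKineticParams(V_I=vi, n=n)

    dm = cfg.demographics
    cp_basal = float(_mean_matched_truncnorm(rng, *dm["cpeptide_b_pmol_l"], size=1)[0])
    g_basal = float(_mean_matched_truncnorm(rng, *dm["glucose_b_mg_dl"], size=1)[0])
    _, basal_sr = cpeptide_steady_state(cp_params, cp_basal)

    peak_time = float(rng.uniform(*cfg.meal_peak_min))
    amplitude = float(rng.uniform(*cfg.meal_amplitude_x_basal)) * basal_sr

    f = float(np.clip(
        rng.normal(cfg.bioavailability_f, cfg.bioavailability_sd), 0.05, 0.95,
    )) if cfg.bioavailability_sd > 0 else cfg.bioavailability_f
    dose = subject.dose_U if subject.dose_U is not None else cfg.dose_U
    iexo, ka = exogenous_pk_profile(subject, dose, cfg, ins_params, f)

    cpsr_mt = true_secretion(basal_sr, amplitude, peak_time, cfg.meal_shape, cfg)
    cpsr_mti = true_secretion(basal_sr, amplitude, peak_time, cfg.meal_shape, cfg, iexo)

    if cfg.pwl_truth:
        # model-matched truth: piecewise-linear interpolants of the smooth curves
        from .secretion import PiecewiseLinearSecretion

        cpsr_mt = PiecewiseLinearSecretion(times, np.asarray(cpsr_mt(times)))
        cpsr_mti = PiecewiseLinearSecretion(times, np.asarray(cpsr_mti(times)))

    cp_mt, iendo_mt = _simulate_truth_series(cp_params, ins_params, cpsr_mt, cp_basal, times)
    cp_mti, iendo_mti = _simulate_truth_series(cp_params, ins_params, cpsr_mti, cp_basal, times)
    i_mt = iendo_mt
    i_mti = iendo_mti + np.asarray(iexo(times))

    # descriptive glucose placeholder (never consumed by the models)
    bump = 40.0 * _gamma_variate(times, 45.0, 2.0)
    g_mt = g_basal + bump
    g_mti = g_basal + bump * (0.85 if cfg.suppression_strength > 0 else 1.0)

    def series(analyte, values, cv):
        vals = np.clip(values, 0.0, None)
        if cfg.noise:
            vals = _lognormal_noise(rng, vals, cv)
        return AnalyteSeries(analyte=analyte, times=times, values=vals, source_unit="")

    glucose_cv = 0.02  # routine glucose assay; placeholder series only
    ds_mt = MealTestDataset(
        subject=subject, arm=ARM_MT,
        glucose=series("glucose", g_mt, glucose_cv),
        insulin=series("insulin", i_mt, cfg.insulin_cv),
        cpeptide=series("cpeptide", cp_mt, cfg.cpeptide_cv),
    )
    ds_mti = MealTestDataset(
        subject=subject, arm=ARM_MT_I,
        glucose=series("glucose", g_mti, glucose_cv),
        insulin=series("insulin", i_mti, cfg.insulin_cv),
        cpeptide=series("cpeptide", cp_mti, cfg.cpeptide_cv),
    )
    truth = TruthRecord(
        cp_params=cp_params, insulin_params=ins_params,
        cpsr_mt=cpsr_mt, cpsr_mt_plus_i=cpsr_mti, iexo=iexo,
        pct_bioavailability=100.0 * f, bioavailability_f=f, absorption_ka=ka,
        basal_sr=basal_sr, cp_basal=cp_basal,
        meal_peak_min=peak_time, meal_amplitude=amplitude, seed=subject_seed,
    )
    return ds_mt, ds_mti, truth


def simulate_cohort(
    cfg: SimulationConfig,
) -> Tuple[List[MealTestDataset], dict]:
    """Simulate the full cohort; returns (datasets, truths-by-subject-id)."""
    subjects = sample_demographics(cfg)
    datasets: List[MealTestDataset] = []
    truths: dict = {}
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(subjects))]
    for subject, child in zip(subjects, child_seeds):
        ds_mt, ds_mti, truth = simulate_meal_test_pair(subject, cfg, subject_seed=child)
        datasets.extend([ds_mt, ds_mti])
        truths[subject.subject_id] = truth
    return datasets, truths
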