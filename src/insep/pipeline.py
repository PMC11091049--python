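"""Cohort-level orchestration of the three-step decomposition.

Per subject with both arms: (1a/1b) deconvolve the C-peptide secretion rate
on each arm, (2a) fit the one-compartment insulin kinetics on the plain
meal-test arm, (2b) predict the endogenous component of the inhaled-insulin
arm with the same parameters, (3) subtract to obtain the exogenous
component, then compute summary metrics and run the comparator corrections.
Subjects missing an arm are skipped with a warning; per-subject failures
quarantine that subject and the run continues.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, wilcoxon

from .comparators import apply_marino_correction, fit_marino_lme, owens_baseline_correction
from .cpeptide import van_cauter_parameters
from .datamodel import ARM_MT, ARM_MT_I, MealTestDataset
from .deconvolution import ErrorModel, FitDiagnostics, deconvolve_cpsr
from .errors import EstimationError
from .insulin import fit_insulin_kinetics, predict_endogenous_component, simulate_endogenous_insulin
from .metrics import decompose, trapezoid_auc
from .units import DEFAULT_UNITS, UnitConversionTable

logger = logging.getLogger("insep")


@dataclass
class PipelineConfig:
    """Knobs of a cohort run."""

    insulin_cv: Optional[float] = None  # None -> profiled
    cpeptide_cv: Optional[float] = None  # None -> profiled
    multistart: int = 5
    seed: int = 0
    auc_interval: tuple = (0.0, None)
    units: UnitConversionTable = field(default_factory=lambda: DEFAULT_UNITS)
    run_comparators: bool = True
    alpha: float = 0.05


@dataclass
class SubjectResult:
    """All per-subject artifacts of one pipeline run."""

    subject_id: str
    cp_params: object
    cpsr_mt: object
    cpsr_mti: object
    diag_deconv_mt: FitDiagnostics
    diag_deconv_mti: FitDiagnostics
    insulin_params: object
    diag_insulin: FitDiagnostics
    iendo_mt: object
    iendo_mti: object
    decomposition: object
    sauc_iendo_mt: float
    sauc_iendo_mti: float
    owens: Optional[dict] = None
    marino: Optional[dict] = None


@dataclass
class CohortReport:
    """Cohort-level tables and statistics."""

    parameter_table: pd.DataFrame
    summary: dict
    per_time: pd.DataFrame
    statistics: dict
    subject_results: Dict[str, SubjectResult]
    skipped: List[str]
    quarantined: Dict[str, str]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.parameter_table.to_csv(outdir / "parameters.csv", index=False)
        self.per_time.to_csv(outdir / "per_time_comparison.csv", index=False)
        (outdir / "summary.json").write_text(json.dumps(self.summary, indent=2, default=float))
        (outdir / "statistics.json").write_text(json.dumps(self.statistics, indent=2, default=float))
        for sid, res in self.subject_results.items():
            d = res.decomposition
            pd.DataFrame({
                "time_min": d.times, "i_total": d.i_total, "i_endo": d.i_endo,
                "i_exo": d.i_exo, "icpr": d.icpr_t,
            }).to_csv(outdir / f"decomposition_{sid}.csv", index=False)


def studentized_residuals(diag: FitDiagnostics) -> np.ndarray:
    """Residual divided by its model-implied SD under the proportional error
    model: r_i = (y_i - yhat_i) / (cv_hat * yhat_i)."""
    return np.asarray(diag.studentized_residuals)


def _pair_datasets(datasets: Iterable[MealTestDataset]):
    by_subject: Dict[str, dict] = {}
    for ds in datasets:
        by_subject.setdefault(ds.subject.subject_id, {})[ds.arm] = ds
    return by_subject


def run_pipeline(
    datasets: Iterable[MealTestDataset],
    config: Optional[PipelineConfig] = None,
) -> CohortReport:
    """Run the full three-step analysis plus comparators on a cohort."""
    cfg = config or PipelineConfig()
    by_subject = _pair_datasets(datasets)

    skipped, quarantined = [], {}
    results: Dict[str, SubjectResult] = {}
    err_cp = ErrorModel(cv=cfg.cpeptide_cv)
    err_ins = ErrorModel(cv=cfg.insulin_cv)

    for sid in sorted(by_subject):
        arms = by_subject[sid]
        if ARM_MT not in arms or ARM_MT_I not in arms:
            warnings.warn(f"subject {sid}: missing an arm, skipped", stacklevel=2)
            skipped.append(sid)
            continue
        ds_mt, ds_mti = arms[ARM_MT], arms[ARM_MT_I]
        try:
            results[sid] = _run_subject(sid, ds_mt, ds_mti, err_cp, err_ins, cfg)
            logger.info("subject %s: pipeline complete", sid)
        except Exception as exc:  # quarantine, never silently drop
            logger.exception("subject %s quarantined", sid)
            quarantined[sid] = f"{type(exc).__name__}: {exc}"

    marino_model = None
    if cfg.run_comparators and len(results) >= 2:
        try:
            marino_model = fit_marino_lme(
                [by_subject[sid][ARM_MT] for sid in results]
            )
        except EstimationError as exc:
            warnings.warn(f"mixed-effects comparator unavailable: {exc}", stacklevel=2)
    if cfg.run_comparators:
        for sid, res in results.items():
            ds_mti = by_subject[sid][ARM_MT_I]
            icpr_o, endo_o, exo_o = owens_baseline_correction(ds_mti.insulin, ds_mti.cpeptide)
            res.owens = {"icpr": icpr_o, "i_endo": endo_o, "i_exo": exo_o}
            if marino_model is not None:
                icpr_m, endo_m, exo_m = apply_marino_correction(
                    marino_model, sid, ds_mti.insulin, ds_mti.cpeptide
                )
                res.marino = {"icpr": icpr_m, "i_endo": endo_m, "i_exo": exo_m}

    parameter_table = pd.DataFrame([
        {
            "subject_id": sid,
            "V_CP1": r.cp_params.V_CP1, "k12": r.cp_params.k12,
            "k21": r.cp_params.k21, "k01": r.cp_params.k01,
            "V_I": r.insulin_params.V_I, "n": r.insulin_params.n,
            "cv_hat_insulin": r.diag_insulin.cv_hat,
            "converged_insulin": r.diag_insulin.converged,
            "sauc_iendo_MT": r.sauc_iendo_mt, "sauc_iendo_MTI": r.sauc_iendo_mti,
            "auc_iexo": r.decomposition.auc_iexo,
            "pct_exo_of_total": r.decomposition.pct_exo_of_total,
            "pct_bioavailability": r.decomposition.pct_bioavailability,
            "n_negative_iexo": r.decomposition.n_negative_iexo,
        }
        for sid, r in results.items()
    ])

    summary = _summaries(parameter_table, results, by_subject, marino_model)
    per_time = _per_time_table(results, by_subject)
    stats = statistics_report(results, by_subject, alpha=cfg.alpha)
    return CohortReport(
        parameter_table=parameter_table,
        summary=summary,
        per_time=per_time,
        statistics=stats,
        subject_results=results,
        skipped=skipped,
        quarantined=quarantined,
    )


def _run_subject(sid, ds_mt, ds_mti, err_cp, err_ins, cfg: PipelineConfig) -> SubjectResult:
    cp_params = van_cauter_parameters(ds_mt.subject)
    sr_mt, diag_1a = deconvolve_cpsr(
        ds_mt.cpeptide, cp_params, err_cp, multistart=cfg.multistart, seed=cfg.seed
    )
    sr_mti, diag_1b = deconvolve_cpsr(
        ds_mti.cpeptide, cp_params, err_cp, multistart=cfg.multistart, seed=cfg.seed
    )
    ins_params, diag_2a = fit_insulin_kinetics(
        ds_mt.insulin, sr_mt, err_ins, multistart=cfg.multistart, seed=cfg.seed
    )
    iendo_mt = simulate_endogenous_insulin(ins_params, sr_mt, ds_mt.insulin.times)
    iendo_mti = predict_endogenous_component(ins_params, sr_mti, ds_mti.insulin.times)
    dose = ds_mti.subject.dose_U
    if dose is None:
        raise EstimationError(f"subject {sid}: inhaled arm present but dose_U missing")
    decomposition = decompose(
        ds_mti.insulin, iendo_mti, ds_mti.cpeptide, ins_params, dose,
        units=cfg.units, auc_interval=cfg.auc_interval,
    )
    sauc_mt = trapezoid_auc(iendo_mt.times, iendo_mt.iendo, supra_basal=True)
    sauc_mti = trapezoid_auc(iendo_mti.times, iendo_mti.iendo, supra_basal=True)
    return SubjectResult(
        subject_id=sid,
        cp_params=cp_params, cpsr_mt=sr_mt, cpsr_mti=sr_mti,
        diag_deconv_mt=diag_1a, diag_deconv_mti=diag_1b,
        insulin_params=ins_params, diag_insulin=diag_2a,
        iendo_mt=iendo_mt, iendo_mti=iendo_mti,
        decomposition=decomposition,
        sauc_iendo_mt=sauc_mt, sauc_iendo_mti=sauc_mti,
    )


def _mean_sd(x) -> dict:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return {"mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan, "n": 0}
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else np.nan,
        "min": float(np.min(x)), "max": float(np.max(x)), "n": int(x.size),
    }


def _summaries(table: pd.DataFrame, results, by_subject, marino_model) -> dict:
    if table.empty:
        return {"n_subjects": 0}
    icpr_dynamic = {
        sid: r.decomposition.icpr_t for sid, r in results.items()
    }
    icpr_dyn_stack = np.array([v for v in icpr_dynamic.values()])
    summary = {
        "n_subjects": int(table.shape[0]),
        "parameters": {
            col: _mean_sd(table[col]) for col in ("V_CP1", "k12", "k21", "k01", "V_I", "n")
        },
        "sauc_iendo_MT": _mean_sd(table["sauc_iendo_MT"]),
        "sauc_iendo_MTI": _mean_sd(table["sauc_iendo_MTI"]),
        "pct_exo_of_total": _mean_sd(table["pct_exo_of_total"]),
        "pct_bioavailability": _mean_sd(table["pct_bioavailability"]),
        "icpr": {
            "dynamic_per_time_mean": [float(v) for v in np.nanmean(icpr_dyn_stack, axis=0)]
            if icpr_dyn_stack.size else [],
            "owens": _mean_sd([r.owens["icpr"] for r in results.values() if r.owens]),
            "marino": _mean_sd([r.marino["icpr"] for r in results.values() if r.marino]),
        },
    }
    if marino_model is not None:
        summary["marino_model"] = {
            "slope": marino_model.slope, "intercept": marino_model.intercept,
            "residual_sd": marino_model.residual_sd, "slope_re_sd": marino_model.slope_re_sd,
        }
    return summary


def _per_time_table(results, by_subject) -> pd.DataFrame:
    rows = []
    for sid, r in results.items():
        ds_mt, ds_mti = by_subject[sid][ARM_MT], by_subject[sid][ARM_MT_I]
        for k, t in enumerate(r.iendo_mt.times):
            rows.append({
                "subject_id": sid, "time_min": float(t),
                "glucose_MT": ds_mt.glucose.values[k] if k < len(ds_mt.glucose) else np.nan,
                "glucose_MTI": ds_mti.glucose.values[k] if k < len(ds_mti.glucose) else np.nan,
                "insulin_MT": ds_mt.insulin.values[k] if k < len(ds_mt.insulin) else np.nan,
                "insulin_MTI": ds_mti.insulin.values[k] if k < len(ds_mti.insulin) else np.nan,
                "cpeptide_MT": ds_mt.cpeptide.values[k] if k < len(ds_mt.cpeptide) else np.nan,
                "cpeptide_MTI": ds_mti.cpeptide.values[k] if k < len(ds_mti.cpeptide) else np.nan,
                "iendo_MT": r.iendo_mt.iendo[k],
                "iendo_MTI": r.iendo_mti.iendo[k],
                "iexo_MTI": r.decomposition.i_exo[k],
            })
    return pd.DataFrame(rows)


def paired_wilcoxon(x, y) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value; identical samples give
    p = 1 by convention (no evidence of a difference)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0 or np.all(d == 0):
        return 1.0
    return float(wilcoxon(d).pvalue)


def lilliefors_pvalue(x) -> float:
    """Lilliefors test of composite normality; NaN when n < 4."""
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4 or np.std(x) == 0:
        return float("nan")
    return float(lilliefors(x, dist="norm")[1])


def statistics_report(results, by_subject, alpha: float = 0.05, min_paired: int = 6) -> dict:
    """Cohort statistics block: normality, per-time paired comparisons,
    supra-basal AUC comparison and sex/BMI stratifications.

    Per-time Wilcoxon p-values are reported unadjusted (a Holm-adjusted
    column accompanies them); stratified comparisons use the rank-sum test.
    """
    sids = sorted(results)
    nsub = len(sids)
    out: dict = {"n_subjects": nsub, "alpha": alpha}
    if nsub < min_paired:
        out["note"] = f"paired statistics omitted: fewer than {min_paired} complete subjects"
        return out

    table = {
        "sauc_iendo_MT": [results[s].sauc_iendo_mt for s in sids],
        "sauc_iendo_MTI": [results[s].sauc_iendo_mti for s in sids],
        "V_I": [results[s].insulin_params.V_I for s in sids],
        "n": [results[s].insulin_params.n for s in sids],
        "pct_bioavailability": [results[s].decomposition.pct_bioavailability for s in sids],
    }
    out["lilliefors_p"] = {k: lilliefors_pvalue(v) for k, v in table.items()}

    times = results[sids[0]].iendo_mt.times
    per_time = []
    for k, t in enumerate(times):
        row = {"time_min": float(t)}
        for label, getter in (
            ("iendo", lambda s: (results[s].iendo_mt.iendo[k], results[s].iendo_mti.iendo[k])),
            ("insulin", lambda s: (by_subject[s][ARM_MT].insulin.values[k],
                                   by_subject[s][ARM_MT_I].insulin.values[k])),
            ("cpeptide", lambda s: (by_subject[s][ARM_MT].cpeptide.values[k],
                                    by_subject[s][ARM_MT_I].cpeptide.values[k])),
            ("glucose", lambda s: (by_subject[s][ARM_MT].glucose.values[k],
                                   by_subject[s][ARM_MT_I].glucose.values[k])),
        ):
            try:
                pairs = [getter(s) for s in sids]
            except IndexError:
                row[f"p_{label}"] = float("nan")
                continue
            x, y = zip(*pairs)
            row[f"p_{label}"] = paired_wilcoxon(x, y)
        per_time.append(row)
    # Holm adjustment across times for the endogenous comparison
    p_endo = np.array([r["p_iendo"] for r in per_time])
    order = np.argsort(p_endo)
    m = p_endo.size
    holm = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_endo[idx])
        holm[idx] = min(1.0, running)
    for r, h in zip(per_time, holm):
        r["p_iendo_holm"] = float(h)
    out["per_time"] = per_time

    out["sauc_wilcoxon_p"] = paired_wilcoxon(table["sauc_iendo_MT"], table["sauc_iendo_MTI"])

    out["stratified"] = {}
    sex = {s: by_subject[s][ARM_MT].subject.sex for s in sids}
    bmi = {s: by_subject[s][ARM_MT].subject.bmi for s in sids}
    strata = {
        "sex_male_vs_female": ([s for s in sids if sex[s] == "male"],
                               [s for s in sids if sex[s] == "female"]),
        "bmi_lt25_vs_ge25": ([s for s in sids if bmi[s] < 25.0],
                             [s for s in sids if bmi[s] >= 25.0]),
    }
    for name, (g1, g2) in strata.items():
        if len(g1) < 2 or len(g2) < 2:
            out["stratified"][name] = {"note": "comparison omitted: a stratum has fewer than 2 subjects"}
            continue
        block = {}
        for var in ("sauc_iendo_MT", "sauc_iendo_MTI", "V_I", "pct_bioavailability"):
            idx = {s: i for i, s in enumerate(sids)}
            x = [table[var][idx[s]] for s in g1]
            y = [table[var][idx[s]] for s in g2]
            block[var] = {
                "group1": _mean_sd(x), "group2": _mean_sd(y),
                "ranksum_p": float(mannwhitneyu(x, y, alternative="two-sided").pvalue),
            }
        out["stratified"][name] = block
    return out
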