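# Methods

This note documents the models, numerical choices and known limitations of
`insep`. Everything quantitative stated here is computed by the test suite
or the acceptance script.

## Models

### C-peptide kinetics (Step 1)

Two-compartment linear model: accessible compartment `q1` (volume `V_CP1`)
exchanging with a peripheral compartment `q2`, irreversible elimination
from the accessible one:

    dq1/dt = -(k01 + k21) q1 + k12 q2 + SR(t)
    dq2/dt =   k21 q1 - k12 q2
    CP(t)  =   q1 / V_CP1

Parameters come from the Van Cauter population method for healthy,
non-obese adults: impulse response `F e^{-a t} + (1-F) e^{-b t}` with
short half-life 4.95 min, `F` = 0.76, long half-life `0.14·age + 29.2` min;
micro-constants `k12 = F·b + (1-F)·a`, `k01 = a·b/k12`,
`k21 = a + b - k12 - k01`; volume `V_CP1 = 1.92·BSA + 0.64` L with DuBois
BSA `0.007184·W^0.425·(100·H)^0.725` (height derived as `sqrt(weight/bmi)`
when not measured). Constants live in `insep/constants.py` with their
citation and can be overridden from a JSON/YAML file. Only the "normal"
population class ships; obese/diabetic constant sets raise
`NotImplementedError`.

Index conventions for `k12`/`k21` differ across the literature; the package
fixes the convention above because it reproduces the published population
triple {0.050, 0.052, 0.059} min⁻¹ at age 28.5 y. Only the value set is
checkable, not the labels.

### Deconvolution (Steps 1a/1b)

CPSR(t) is continuous piecewise-linear with breakpoints at the C-peptide
sampling times and constant extrapolation beyond the last. The node at
t = 0 is fixed at the basal rate `sr0 = k01·V_CP1·CP(0)` implied by the
fasting steady state (the source method does not state whether this node
was estimated; fixing it matches the steady-state initialisation style of
the insulin model and makes the noise-free problem square). The remaining
nodes are estimated by maximising a Gaussian likelihood with proportional
error (SD = cv·prediction), subject to node ≥ 0.

Because the kinetics are linear, the predicted C-peptide is affine in the
nodes, `CP_pred = d + B s`; `d` and `B` are built exactly with one 4×4
matrix exponential per inter-sample segment (state augmented with the input
value and slope). On noise-free model-matched data the problem is square
and nonsingular and the estimate equals the direct linear solve (verified
to ≤1e-6 relative against an independent stiff-ODE oracle). Optimisation:
L-BFGS-B with analytic gradient from two deterministic starts (clipped
linear solve; flat basal profile) plus seeded log-normal jittered restarts
(default 5). Tolerances: ftol 1e-12, gtol 1e-10.

The error CV is profiled out in closed form by default (the source names
maximum likelihood but no variance model; the assay CVs motivate a
proportional one) and can be fixed to the assay CV instead. Two numerical
notes: (i) the profiled variance is floored at cv² = 1e-16 so the
likelihood stays bounded on perfect fits — at the floor the estimate sits
within ~1e-8 relative of the interpolant; (ii) with a *fixed* cv the exact
ML solution is shrunk below the interpolant by the `Σ log(prediction)`
normalisation term, an O(cv²) effect — this is a property of the
likelihood, not an implementation artefact. No regularisation by default;
an optional squared-second-difference penalty exists (off, and unused by
all shipped analyses).

### Insulin kinetics (Steps 2a/2b)

One compartment, `dA/dt = -n·A + CPSR(t)`, `A(0) = CPSR(0)/n`,
`Iendo = A/V_I`, solved in closed form per linear segment of the input.
Hepatic extraction is deliberately not modelled; `V_I` and `n` absorb it,
which is why fitted `V_I` exceeds anatomical plasma volume. The (V_I, n)
fit maximises the same proportional-error likelihood over log-parameters
(L-BFGS-B; bounds V_I ∈ [1, 100] L, n ∈ [1e-3, 1] min⁻¹; start
n₀ = 0.12 min⁻¹ and V₀ matching the fasting sample, plus seeded jittered
restarts). Step 2b reuses the MT-arm parameters unchanged on the MT+I
secretion input — the method's central assumption is that each subject's
insulin kinetics are the same in both tests.

Identifiability: the data constrain the product `n·V_I` strongly (it sets
the quasi-steady gain CPSR/Iendo) but the split only through the fast early
transients. A warning is raised when the estimated (V_I, n) correlation
exceeds 0.999, the FD Hessian is near-singular, or — the robust check — a
±25% joint shift along the constant-product ridge costs less than 0.05
negative-log-likelihood units.

### Decomposition and metrics (Step 3)

`i_exo(tᵢ) = i_total(tᵢ) - i_endo(tᵢ)` with negatives retained (clipping
would bias exposure upward) and counted. Quadrature is trapezoidal on the
sample times; `AUC_Iexo` uses [0, 360] min and baseline 0 (no exogenous
insulin pre-dose); supra-basal AUC subtracts the t = 0 value and includes
negative increments (a truncate-at-zero option exists, off by default).
Absolute bioavailability divides `AUC_Iexo` by `Dose/(V_I·n)` — the
printed source formula has this reference AUC inverted, which is
dimensionally inconsistent; the package uses the consistent form. %exo is
invariant to the insulin µU/mL→pmol/L factor (it cancels against the fitted
V_I) and scales inversely with the U→pmol factor.

### Comparators

Owens: `ICPR = I(0)/CP(0)`, `Iendo = ICPR·CP(t)`. Marino:
`I = (Slope + v_subject)·CP + Intercept + ε` fitted by ML (not REML, for
consistency with the pipeline) on all MT time points of all subjects with
equal weight, random slope only. The mixed model is fitted with both a
gradient (lbfgs) and a direct-search (powell) optimiser and the higher
finite likelihood kept, because the gradient path can collapse the
random-slope variance to a degenerate local optimum; when the variance is
estimated at zero the subject deviations are reported as zero. Canonical
units (pmol/L) are used in the regression; a unit change would rescale
Slope/Intercept but not the resulting decomposition.

## Synthetic cohort generator

The generator emulates the targeted study design and provides ground truth;
its defaults are the study conditions:

| parameter | default | basis |
|---|---|---|
| n_subjects | 21 | study size |
| time grid | 0, 7, 15, 30, 60, 120, 240, 300, 360 min | study protocol |
| insulin / C-peptide CV | 0.045 / 0.085 | stated assay CVs (4–5%, 8–9%) |
| dose | 22 U | study dose (22 or 20 U) |
| demographics | age 28.5 ± 8.6 y, weight 76.8 ± 13.5 kg, BMI 26.5 ± 3.0 | study cohort table |
| fasting glucose / C-peptide | 89.0 ± 6.7 mg/dL, 430 ± 199 pmol/L | study cohort table |
| V_I, n truth | 15.68 ± 5.74 L, 0.120 ± 0.050 min⁻¹ | study estimates as population |
| bioavailability f | 0.42 ± 0.21, truncated to [0.05, 0.95] | study %exo 42 ± 21% |
| absorption peak | 15 min | reported fast onset of the inhaled formulation |
| suppression_strength | 8.0 | calibrated: see below |

Demographic and kinetic draws use truncated normals whose location is
shifted so the *truncated* mean equals the target (physiologic bounds:
age [18, 55], weight [45, 120], BMI [18.5, 35], n [0.05, 0.30],
V_I [6, 35]). Fasting insulin is not drawn independently — it is implied by
`I_b = SR_b/(n·V_I)`, keeping each subject internally consistent.

True secretion is basal plus a biphasic meal response: an early
gamma-variate burst (shape 2, peak uniform in 40–80 min, amplitude uniform
in 3–6 × basal) mixed 50/50 with a stretched, flatter second phase
(peak at 2.5× the burst peak, shape 1.2) that keeps secretion above basal
through the 6-h test, as meal data show. The smooth truth is deliberately
outside the piecewise-linear model class so recovery tests expose the
approximation error honestly; `pwl_truth=True` switches to a model-matched
piecewise-linear truth for exactness tests.

The exogenous dose follows first-order (Bateman) absorption of the
bioavailable fraction with the absorption rate solved per subject so the
plasma peak lands at 15 min given that subject's `n` (flip-flop kinetics
when 1/n < 15 min); the profile is <1% of peak past 240 min. In the MT+I
arm the meal component of secretion is multiplied by
`1/(1 + strength·Iexo(t)/100 pmol/L)`, a stand-in for the negative insulin
feedback on secretion — a testing device, not a physiological model.
`strength = 8.0` is calibrated once so the true endogenous supra-basal AUC
ratio MT+I/MT averages ≈ 0.48 over 21-subject cohorts, matching the
roughly-twofold reduction the method is meant to detect; the hyperbolic
form saturates, so near-complete suppression at the exogenous peak is
required to halve the 6-h exposure.

Noise is multiplicative mean-one log-normal, independent across analytes
and times. Glucose is a descriptive placeholder curve (the models never
consume it). All randomness flows from a single seed through per-subject
spawned substreams keyed by a stable CRC of the subject id, so cohorts are
reproducible and per-subject reruns independent.

What passing tests on this generator do **not** show about real data: no
population-vs-individual mismatch in the C-peptide kinetic constants (the
analysis assumes the same Van Cauter parameters the generator uses), no
carry-over between test days, no assay bias or drift, no within-day
variation of hepatic extraction, and a feedback form chosen for
convenience.

## Measured accuracy (synthetic conditions, computed in the test suite)

- Model-matched noise-free data: deconvolution nodes and (V_I, n) recovered
  to ≤1e-6 and ≤1e-3 relative respectively; exogenous profile ≤1% of peak.
- Smooth-truth noise-free data: the piecewise-linear approximation biases
  (V_I, n) by a few percent (asserted ≤5%) and the exogenous profile by up
  to ~2% of its peak (asserted ≤3%).
- At assay CVs (50 subjects): median |relative error| of the
  bioavailability percentage ≈ 6%; V_I and n individually carry ≈30%
  median error because the likelihood is nearly flat along the constant-
  `n·V_I` ridge — a single 9-point meal test does not separate them more
  finely. Their product, which the bioavailability depends on, is
  well determined.
- Cohort pattern: with the calibrated suppression, the paired Wilcoxon on
  supra-basal endogenous AUC rejects at α = 0.01 in ≥90/100 replicate
  21-subject cohorts (observed 100/100), mean ratio ≈ 0.48.

Problem sizes in the shipped tests (replicate counts, cohort sizes) are the
package's choices to keep the default suite brisk; all scale up via the
public APIs.

## Statistics block

Lilliefors tests composite normality per summary variable; measured
analytes and predicted endogenous profiles are compared between arms at
each sampling time with the paired Wilcoxon signed-rank test (p-values
reported unadjusted, mirroring per-time significance marking, with a Holm
column alongside); supra-basal AUCs likewise; sex and BMI (<25 vs ≥25)
strata are compared with the rank-sum test. All-zero paired differences
report p = 1. Paired statistics require ≥6 complete subjects; degenerate
strata are omitted with a note. Studentized residuals are
`(y - ŷ)/(cv̂·ŷ)`; under a correctly specified proportional model with the
CV fixed at truth their pooled SD is slightly below 1 (two parameters
absorb part of nine residual degrees of freedom).

## Known limitations

- Population C-peptide kinetics ignore inter-subject variation beyond age
  and BSA; individual kinetics would need separate experiments.
- The even-determined deconvolution interpolates measurement noise into the
  secretion estimate; no smoothing is applied by default (by design).
- V_I/n split identifiability is weak at realistic noise (see above).
- The one-compartment insulin model assumes linear dynamics (appropriate at
  meal-test insulin levels, not at clamp levels).
- The bioavailability reference AUC assumes the fitted kinetics apply to an
  intravenous route, i.e. kinetics independent of the administration route.
- Subjects missing an arm are skipped; failing subjects are quarantined and
  reported, never silently dropped.
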