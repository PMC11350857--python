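# Methods

This note is the package's own scientific account: the model it implements,
the numerical choices behind the estimation machinery, what the synthetic
data generator does and does not claim, and the package's known limitations.

## Structural model

Ceftazidime disposition is modelled as one compartment with first-order
elimination.  Every dosing event is a zero-order input (an `amount` infused
over `duration`; `duration = 0` is the bolus limit, `duration = inf` an
open-ended maintenance infusion).  Linearity gives the concentration under an
arbitrary regimen as the superposition of single-event solutions:

- during an infusion at rate `R0` started at `t0`:
  `C(t) = R0/CL * (1 - exp(-k (t - t0)))`, `k = CL/V`
- after it ends at `t0 + D`:
  `C(t) = R0/CL * (1 - exp(-k D)) * exp(-k (t - t0 - D))`
- a bolus contributes `amount/V * exp(-k (t - t0))`.

Derived quantities are closed-form: half-life `ln 2 * V/CL`, steady state
`Css = rate/CL`.  `time_to_threshold` scans a 0.1 h grid and refines the
bracketing interval by bisection to 0.01 h, extending the horizon only while
the asymptotic steady state still exceeds the threshold, so the answer never
depends on the grid or horizon.

## Population model

| parameter | meaning | default | units |
| --- | --- | --- | --- |
| `CL_pop` | typical clearance at the reference GFR | 4.45 | L/h |
| `V_pop` | typical volume of distribution | 88 | L |
| `beta_GFR_CL` | GFR exponent on clearance | 0.9 | – |
| `GFR_median_ref` | reference GFR | 73.90 | mL/min/1.73 m² |
| `omega_CL` | SD of the log-scale CL random effect | 0.46 | – |
| `omega_V` | SD of the log-scale V random effect | 0.57 | – |
| `sigma_add` | additive residual SD | 0.39 | mg/L |

`CL_i = CL_pop (GFR_i/73.90)^0.9 e^{eta_CL}`, `V_i = V_pop e^{eta_V}`, etas
independent by default (a correlation hook exists).  Residual error is
additive Gaussian on the concentration scale.  Observations below the assay
LLOQ of 8 mg/L are recorded as 4 mg/L; the likelihood uses the substituted
value as recorded, deliberately without censored-likelihood handling, to
match how such data reach the analyst from routine TDM.

GFR can be computed from serum creatinine by the CKD-EPI 2009 equation
(race coefficient off by default).

## Synthetic cohort generator

No patient-level data ship with the package; the generator produces cohorts
with the development population's *summary* structure: 86 subjects by
default, GFR lognormal with arithmetic mean 87.6 and SD 74.2 truncated to
[10, 300] mL/min/1.73 m² (the truncation lowers the realized moments to
~81/56; tests check against the truncated distribution's exact moments),
weight 91.3 ± 25.3 kg, age 64.5 ± 11.9 y, 77.9% male, a 2 g/0.5 h loading
dose followed by an individualized continuous infusion around 6 g/day, and
1-9 samples per subject drawn uniformly on [6, 96] h.  Values are rounded to
the CSV dialect's two decimals and the LLOQ rule re-applied after rounding.

Each subject draws from an independent child stream of the master seed keyed
by subject index, so enlarging or reordering a cohort never changes existing
subjects.  These are *design-matched* synthetic patients: they reproduce the
published marginal summaries, not the joint covariate structure (e.g. any
GFR-weight correlation) of the real cohorts.

## Estimation

The marginal likelihood integrates the two random effects out of each
subject's joint density.  The fit maximizes a Laplace approximation around
the per-subject MAP etas: the inner problems for all subjects are solved
simultaneously by a damped Gauss-Newton iteration with analytic 2x2 solves
and finite-difference Jacobians, and the Laplace determinant uses full
finite-difference Hessians.  The outer optimization is Nelder-Mead on
log-transformed scale parameters (the GFR exponent stays natural-scale),
with jittered multi-start: short pre-runs rank the starts, the best is
polished.  Non-convergence is reported, never silenced.

**Why a nested adaptive quadrature exists alongside Laplace.**  The residual
SD (0.39 mg/L) is tiny relative to typical concentrations, so a subject's
posterior in `(eta_CL, eta_V)` is a thin ridge: near steady state the data
pin `eta_CL` to ~0.01 width while `eta_V` stays prior-wide, and before
steady state the ridge curves.  A single Gaussian centered at the MAP can
misstate such an integral by tens of percent for a minority of subjects —
plain Laplace fails a 0.5% quadrature-agreement check on realistic synthetic
subjects.  `marginal_ofv(..., method="agq")` therefore evaluates the
integral by *nested* adaptive quadrature: 41 Gauss-Hermite nodes across
`eta_V`, and at each node a batched 1-D Newton tracks the conditional mode
of `eta_CL` before 9 inner Gauss-Hermite nodes integrate across the ridge.
This evaluation agrees with brute-force dense-grid quadrature to well under
0.5% per subject and is the reference against which the tests check the
likelihood; the cheaper Laplace version drives the optimizer, where only the
location of the optimum matters.

Empirical-Bayes (MAP) etas provide individual predictions, shrinkage
(`1 - SD(eta)/omega`) and the paired 24 h/48 h comparison.  Nested models
are compared by likelihood-ratio test (chi-square, strict threshold).

## Validation

External validation uses per-observation prediction errors
`PE% = 100 (pred - obs)/obs` summarized by the median (MDPE, bias) and
median absolute value (MDAPE, inaccuracy), acceptable at |MDPE| <= 20% and
MDAPE <= 30%, evaluated on empirical-Bayes individual predictions (the level
at which TDM models are used).  LLOQ-substituted observations are excluded
from PE by default — an error against a reporting convention is not
informative.  The visual predictive check keeps the observed design fixed,
simulates replicate datasets, and compares observed percentiles with
across-replicate bands in equal-count time bins, optionally
prediction-corrected.

## Dosing design

The coverage-based loading dose is `LD = Vd * TC * exp(kappa * omega_V)`
with `TC = 60 mg/L` and `kappa` the standard-normal quantile of the desired
coverage (0.84 for 80%, used at two decimals as printed in the source
formula).  A literature table carries nine published ICU models; rows
without a published `omega_V` carry their authors' reported loading dose.

The Monte Carlo regimen simulator draws GFR from the study population's
truncated lognormal and etas from the interindividual model, evaluates all
profiles in closed form on a 0.1 h grid over 72 h, and reports the delay to
a 35 mg/L target.  **Attainment is judged against sustained exposure**: a
subject counts as reaching the target only if their maintenance steady state
is at least the threshold; a transient loading-dose overshoot that falls
back below target is not attainment.  This makes the never-fraction a
property of the clearance distribution alone, identical across loading doses
at matched seeds — the invariant the tests rely on.  For attaining subjects
whose profiles are still climbing at 72 h the crossing time is extended
analytically from the monotone tail.  Medians treat never-attainers as
right-censored at +inf.

At the defaults (3000 subjects, seed-reproducible) the median delay under a
2 g load plus 6 g/day is ~13-14 h versus ~0.5 h under a 4 g load, with ~22%
of patients never reaching 35 mg/L at 6 g/day regardless of the load.

## Problem sizes

Defaults are the package's own choices and mirror the study conditions: 86
subjects per synthetic cohort, 3000 subjects per Monte Carlo regimen run,
10 replicates in the parameter-recovery experiment.  One 86-subject fit
takes ~5-25 s on a single CPU (multi-start); the full recovery experiment
~3-5 min.  Nelder-Mead tolerances default to 0.2% on the log-scale
parameters — an order of magnitude below the parameters' sampling
uncertainty; tightening them 10-fold changes estimates only in the fourth
significant digit at ~40x the cost.

## Limitations

- One compartment, additive error: no two-compartment option and no
  proportional or combined error model.
- LLOQ handling reproduces the substitution convention; the likelihood does
  not integrate over the censored region (M3), which would be the better
  statistical treatment if raw sub-LLOQ records were available.
- Synthetic cohorts match marginal summaries only; joint covariate
  dependence is not modelled, so covariate-coefficient recovery experiments
  inherit that simplification.
- The volume of distribution is weakly identified under sparse
  near-steady-state sampling (most samples carry information about CL only);
  recovery tolerances for `V_pop` are accordingly wide and the eta_V
  posterior is often prior-dominated.
- The GFR exponent is estimated on its natural scale without constraints; no
  standard errors are reported by default (`FitSettings.compute_rse`
  enables a finite-difference approximation).
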