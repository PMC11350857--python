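"""Fit the mixed-effects model to a synthetic cohort and validate it.

Generates a 30-subject dataset from the published parameters, refits the
model by Laplace marginal maximum likelihood, tests the GFR covariate by a
likelihood-ratio test, and reports empirical-Bayes prediction errors
(acceptable when |MDPE| <= 20% and MDAPE <= 30%).

Runtime: a minute or two on one CPU.
"""

from ceftazpk import (
    CohortConfig,
    FitSettings,
    PopulationParameters,
    fit_population,
    generate_cohort,
    generate_tdm_dataset,
    marginal_ofv,
    mdpe_mdape,
    prediction_errors,
)
from ceftazpk.estimation import lrt_covariate
from ceftazpk.validation import individual_predictions

truth = PopulationParameters()
config = CohortConfig(n_subjects=30, seed=5)
dataset = generate_tdm_dataset(generate_cohort(config), truth, config)

fit = fit_population(dataset, init=truth, settings=FitSettings(n_starts=1))
e = fit.estimates
print(f"converged: {fit.converged}   OFV: {fit.ofv:.2f}   evaluations: {fit.n_evaluations}")
print(f"CL_pop {e.CL_pop:.2f} L/h (truth 4.45)   V_pop {e.V_pop:.1f} L (truth 88)")
print(f"beta_GFR_CL {e.beta_GFR_CL:.2f} (truth 0.9)")
print(f"omega_CL {e.omega_CL:.2f}   omega_V {e.omega_V:.2f}   sigma {e.sigma_add:.2f} mg/L")
print(f"shrinkage: CL {100 * fit.shrinkage_CL:.0f}%   V {100 * fit.shrinkage_V:.0f}%")

# is the GFR effect on clearance supported? (chi-square, 1 df, alpha 0.05)
ofv_no_cov = marginal_ofv(dataset, e.replace(beta_GFR_CL=0.0))
delta, significant = lrt_covariate(ofv_no_cov, fit.ofv)
print(f"LRT for the GFR covariate: delta OFV {delta:.1f} -> significant: {significant}")

pred, obs = individual_predictions(dataset, e)
summary = mdpe_mdape(prediction_errors(pred, obs))
print(f"MDPE {summary.mdpe:+.1f}%   MDAPE {summary.mdape:.1f}%   acceptable: {summary.acceptable}")
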