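"""Predictive-performance metrics: prediction errors, VPC, paired comparisons.

External validation of a population PK model conventionally reports the
per-observation prediction error

    PE% = 100 * (Cpred - Cobs) / Cobs

summarized by its median (MDPE, bias) and the median absolute value
(MDAPE, inaccuracy); the model is acceptable when |MDPE| <= 20% and
MDAPE <= 30%.  The visual predictive check (VPC) compares observed
percentiles against simulation-based percentile bands, optionally
prediction-corrected.  The paired 24 h vs 48 h comparison quantifies how
far from steady state individual predictions still are a day into therapy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TdmDataset
from .estimation import FitResult, empirical_bayes
from .pk import concentration
from .population import (
    LLOQ_SUBSTITUTE,
    PopulationParameters,
    individual_parameters,
    sample_etas,
)

__all__ = [
    "PredictionErrorSummary",
    "prediction_errors",
    "mdpe_mdape",
    "vpc",
    "paired_prediction_comparison",
]


@dataclass(frozen=True)
class PredictionErrorSummary:
    """Bias (MDPE) and inaccuracy (MDAPE) of a set of prediction errors."""

    pe: np.ndarray  # per-observation PE (%)
    mdpe: float  # %
    mdape: float  # %
    acceptable: bool

    #: acceptability limits (|MDPE| and MDAPE, in %)
    MDPE_LIMIT = 20.0
    MDAPE_LIMIT = 30.0


def prediction_errors(pred: Sequence[float], obs: Sequence[float]) -> np.ndarray:
    """Per-pair prediction error, 100*(pred-obs)/obs, in percent."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    if (obs <= 0).any():
        raise ValueError("observed concentrations must be positive")
    return 100.0 * (pred - obs) / obs


def mdpe_mdape(pe: Sequence[float]) -> PredictionErrorSummary:
    """Median (MDPE) and median-absolute (MDAPE) prediction error.

    Medians use conventional midpoint interpolation for even lengths.
    Acceptable iff |MDPE| <= 20% and MDAPE <= 30%.
    """
    pe = np.asarray(pe, dtype=float)
    if pe.size == 0:
        raise ValueError("empty prediction-error list")
    mdpe = float(np.median(pe))
    mdape = float(np.median(np.abs(pe)))
    return PredictionErrorSummary(
        pe=pe,
        mdpe=mdpe,
        mdape=mdape,
        acceptable=(abs(mdpe) <= PredictionErrorSummary.MDPE_LIMIT)
        and (mdape <= PredictionErrorSummary.MDAPE_LIMIT),
    )


def population_predictions(
    dataset: TdmDataset,
    pop: PopulationParameters,
    exclude_lloq_substituted: bool = True,
    lloq_substitute: float = LLOQ_SUBSTITUTE,
) -> tuple[np.ndarray, np.ndarray]:
    """Typical-subject (eta = 0) predictions aligned with the observations.

    Sub-LLOQ substituted observations are excluded by default: a PE against
    a reporting convention rather than a measurement is not meaningful.
    """
    preds, obs_all = [], []
    from .population import RandomEffects

    for subject, regimen, times, obs in dataset.subject_records():
        params = individual_parameters(pop, subject, RandomEffects(0.0, 0.0))
        p = concentration(regimen, params, times)
        keep = np.ones(len(obs), dtype=bool)
        if exclude_lloq_substituted:
            keep = obs != lloq_substitute
        preds.append(p[keep])
        obs_all.append(obs[keep])
    return np.concatenate(preds), np.concatenate(obs_all)


def individual_predictions(
    dataset: TdmDataset,
    pop: PopulationParameters,
    exclude_lloq_substituted: bool = True,
    lloq_substitute: float = LLOQ_SUBSTITUTE,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical-Bayes (MAP) predictions aligned with the observations.

    Each subject's random effects are estimated from their own observations
    under ``pop``; predictions then use the resulting individual parameters.
    This is the prediction level at which external validation is usually
    reported for TDM models.
    """
    from .estimation import _Design, _laplace_components

    design = _Design(dataset)
    _, eta = _laplace_components(design, pop)
    pred = design.predict(pop, eta)
    keep = np.ones(len(pred), dtype=bool)
    if exclude_lloq_substituted:
        keep = design.y != lloq_substitute
    return pred[keep], design.y[keep]


def vpc(
    dataset: TdmDataset,
    pop: PopulationParameters,
    n_sim: int = 500,
    bins: int = 6,
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0),
    prediction_corrected: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile visual predictive check.

    The observed design (subjects, regimens, sampling times) is kept fixed;
    ``n_sim`` replicate datasets are simulated from ``pop`` (new etas and
    residuals each time, without LLOQ substitution so the percentile bands
    are smooth).  Observations are pooled into ``bins`` equal-count time
    bins; per bin the observed percentiles are compared with the across-
    replicate 5th/95th percentile band of each simulated percentile.  With
    ``prediction_corrected`` both observed and simulated values are rescaled
    by (bin-median population prediction) / (subject-time population
    prediction) before binning.

    Returns one row per bin with observed and simulated-band columns.
    """
    rng = np.random.default_rng(seed)
    records = list(dataset.subject_records())
    times = np.concatenate([t for _, _, t, _ in records])
    obs = np.concatenate([y for _, _, _, y in records]).astype(float)

    from .population import RandomEffects

    popred = np.concatenate(
        [
            concentration(reg, individual_parameters(pop, subj, RandomEffects(0.0, 0.0)), t)
            for subj, reg, t, _ in records
        ]
    )

    # equal-count bin edges on time
    qs = np.linspace(0, 100, bins + 1)
    edges = np.percentile(times, qs)
    edges[-1] += 1e-9
    bin_idx = np.clip(np.digitize(times, edges) - 1, 0, bins - 1)

    if prediction_corrected:
        corr = np.ones_like(obs)
        for b in range(bins):
            m = bin_idx == b
            med = np.median(popred[m])
            corr[m] = med / np.where(popred[m] > 0, popred[m], np.nan)
        obs_used = obs * corr
    else:
        corr = np.ones_like(obs)
        obs_used = obs

    sims = np.empty((n_sim, len(obs)))
    for s in range(n_sim):
        vals = []
        for subj, reg, t, _ in records:
            params = individual_parameters(pop, subj, sample_etas(pop, rng))
            c = concentration(reg, params, t)
            vals.append(c + pop.sigma_add * rng.standard_normal(len(t)))
        sims[s] = np.concatenate(vals) * corr

    rows = []
    for b in range(bins):
        m = bin_idx == b
        row = {"bin": b, "t_mid": float(np.median(times[m])), "n_obs": int(m.sum())}
        for p in percentiles:
            row[f"obs_p{p:g}"] = float(np.percentile(obs_used[m], p))
            sim_p = np.percentile(sims[:, m], p, axis=1)  # per replicate
            row[f"sim_p{p:g}_lo"] = float(np.percentile(sim_p, 5))
            row[f"sim_p{p:g}_med"] = float(np.percentile(sim_p, 50))
            row[f"sim_p{p:g}_hi"] = float(np.percentile(sim_p, 95))
        rows.append(row)
    return pd.DataFrame(rows)


def paired_prediction_comparison(
    fit: FitResult,
    dataset: TdmDataset,
    t1: float = 24.0,
    t2: float = 48.0,
    window: float = 4.0,
) -> dict:
    """Compare individual predicted concentrations at two times (paired t-test).

    Individual predictions use each subject's empirical-Bayes parameters
    from ``fit``.  Only subjects whose dose events are unchanged between
    ``t1 - window`` and ``t2 + window`` are included, mirroring the
    unchanged-dose inclusion rule.  The times themselves are the nominal
    ``t1`` and ``t2`` (the +/- window applies to the dose-stability check).

    Returns means at both times, mean paired difference, the t statistic
    and the two-sided p-value.
    """
    c1, c2 = [], []
    for subject, regimen, _, _ in dataset.subject_records():
        # dose stability: no event starting inside the comparison span
        if any(t1 - window < e.start_time <= t2 + window for e in regimen.events
               if e.start_time > t1 - window):
            continue
        etas = fit.etas.get(subject.id)
        if etas is None:
            continue
        params = individual_parameters(fit.estimates, subject, etas)
        c = concentration(regimen, params, [t1, t2])
        c1.append(c[0])
        c2.append(c[1])
    c1 = np.asarray(c1)
    c2 = np.asarray(c2)
    if len(c1) < 2:
        raise ValueError("need at least two eligible subjects")
    diff = c2 - c1
    if np.allclose(diff, 0.0):
        tstat, pval = 0.0, 1.0
    else:
        tstat, pval = stats.ttest_rel(c2, c1)
    return {
        "n": int(len(c1)),
        "mean_t1": float(np.mean(c1)),
        "sd_t1": float(np.std(c1, ddof=1)),
        "mean_t2": float(np.mean(c2)),
        "sd_t2": float(np.std(c2, ddof=1)),
        "mean_difference": float(np.mean(diff)),
        "t_statistic": float(tstat),
        "p_value": float(pval),
    }
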