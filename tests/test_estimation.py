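"""Marginal likelihood vs an independent quadrature oracle, recovery, EBEs."""

import math

import numpy as np
import pytest

from ceftazpk import (
    CohortConfig,
    FitSettings,
    PopulationParameters,
    RandomEffects,
    TdmDataset,
    empirical_bayes,
    fit_population,
    generate_cohort,
    generate_tdm_dataset,
    lrt_covariate,
    marginal_ofv,
    shrinkage,
)
from ceftazpk.estimation import LikelihoodError, subject_ofvs

LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# independent oracle: closed-form kinetics + dense-grid 2-D quadrature,
# written from scratch in the test (no calls into the package's solvers)


def _oracle_concentration(events, CL, V, t):
    """One-compartment superposition for finite-duration zero-order inputs.

    ``CL``/``V`` may be grids; ``t`` is a 1-D array of times.  Returns an
    array broadcast to grid.shape + t.shape.
    """
    k = CL / V
    out = 0.0
    for start, amount, duration in events:
        rel = t - start
        if duration == 0:
            out = out + np.where(rel >= 0, (amount / V)[..., None] * np.exp(-k[..., None] * np.maximum(rel, 0)), 0.0)
            continue
        rate = amount / duration
        css = (rate / CL)[..., None]
        kk = k[..., None]
        during = (rel > 0) & (rel <= duration)
        after = rel > duration
        out = out + np.where(during, css * (1 - np.exp(-kk * np.maximum(rel, 0))), 0.0)
        out = out + np.where(
            after,
            css * (1 - np.exp(-kk * duration)) * np.exp(-kk * np.maximum(rel - duration, 0)),
            0.0,
        )
    return out


def _oracle_h(e1, e2, gfr, events, t, y, pop):
    """Joint negative log density h(eta) on a (n1-grid, n2-grid) mesh."""
    E1, E2 = np.meshgrid(e1, e2, indexing="ij")
    CL = pop.CL_pop * (gfr / pop.GFR_median_ref) ** pop.beta_GFR_CL * np.exp(E1)
    V = pop.V_pop * np.exp(E2)
    f = _oracle_concentration(events, CL, V, t)
    r = y - f
    s2 = pop.sigma_add**2
    h = (r**2).sum(axis=-1) / (2 * s2) + 0.5 * len(y) * (LOG_2PI + math.log(s2))
    h += 0.5 * (E1 / pop.omega_CL) ** 2 + 0.5 * (LOG_2PI + 2 * math.log(pop.omega_CL))
    h += 0.5 * (E2 / pop.omega_V) ** 2 + 0.5 * (LOG_2PI + 2 * math.log(pop.omega_V))
    return h


def oracle_minus2loglik(subject, regimen, times, obs, pop):
    """-2 log of the marginal likelihood by two-stage dense trapezoid quadrature."""
    events = [(e.start_time, e.amount, e.duration) for e in regimen.events]
    gfr = subject.GFR

    # stage 1: coarse scan to find the posterior ridge
    e1c = np.linspace(-2.0, 2.0, 241)
    e2c = np.linspace(-2.8, 2.8, 241)
    hc = _oracle_h(e1c, e2c, gfr, events, times, obs, pop)
    hmin = hc.min()
    # e2 rows carrying mass, and the conditional e1 ridge across them
    row_min = hc.min(axis=0)  # over e1, per e2
    live = row_min < hmin + 40.0
    ridge_e1 = e1c[hc[:, live].argmin(axis=0)]
    lo1, hi1 = ridge_e1.min() - 0.35, ridge_e1.max() + 0.35
    lo2, hi2 = e2c[live].min() - 0.35, e2c[live].max() + 0.35

    # stage 2: fine grid; the ridge across e1 is ~sigma/|df/deta| wide, so
    # keep the e1 spacing below ~1e-3
    n1 = max(1500, int((hi1 - lo1) / 8e-4))
    e1 = np.linspace(lo1, hi1, n1)
    e2 = np.linspace(lo2, hi2, 901)
    h = _oracle_h(e1, e2, gfr, events, times, obs, pop)
    hmin = h.min()
    integrand = np.exp(-(h - hmin))
    inner = np.trapezoid(integrand, e1, axis=0)
    L_scaled = np.trapezoid(inner, e2)
    return 2.0 * hmin - 2.0 * math.log(L_scaled)


def _subset(dataset, ids):
    return TdmDataset(dataset.data[dataset.data["ID"].isin(ids)].reset_index(drop=True))


class TestMarginalLikelihood:
    def test_matches_quadrature_oracle_within_half_percent(self, small_dataset, pop):
        records = {s.id: (s, reg, t, y) for s, reg, t, y in small_dataset.subject_records()}
        # a spread of sampling richness: sparse and rich subjects
        by_n = sorted(records, key=lambda sid: len(records[sid][2]))
        chosen = [by_n[0], by_n[len(by_n) // 2], by_n[-1], by_n[-2]]
        sub = _subset(small_dataset, chosen)
        got = dict(zip(sub.subject_ids(), subject_ofvs(sub, pop, method="agq")))
        for sid in chosen:
            subject, regimen, times, obs = records[sid]
            want = oracle_minus2loglik(subject, regimen, times, obs, pop)
            assert got[sid] == pytest.approx(want, rel=0.005), f"subject {sid}"

    def test_subject_ofvs_sum_to_total(self, small_dataset, pop):
        for method in ("laplace", "agq"):
            parts = subject_ofvs(small_dataset, pop, method)
            assert parts.sum() == pytest.approx(marginal_ofv(small_dataset, pop, method), rel=1e-12)

    def test_invariant_to_subject_order(self, small_dataset, pop):
        d = small_dataset.data
        ids = small_dataset.subject_ids()
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(ids))
        shuffled = TdmDataset(
            __import__("pandas").concat([d[d["ID"] == i] for i in perm]).reset_index(drop=True)
        )
        assert marginal_ofv(shuffled, pop) == pytest.approx(marginal_ofv(small_dataset, pop), rel=1e-9)

    def test_zero_omegas_give_least_squares_deviance(self, small_dataset, pop):
        # with no random effects the integral collapses: OFV is the
        # fixed-effects Gaussian deviance, computable directly
        p0 = pop.replace(omega_CL=0.0, omega_V=0.0)
        want = 0.0
        for subject, regimen, times, obs in small_dataset.subject_records():
            events = [(e.start_time, e.amount, e.duration) for e in regimen.events]
            CL = np.array([p0.CL_pop * (subject.GFR / p0.GFR_median_ref) ** p0.beta_GFR_CL])
            V = np.array([p0.V_pop])
            f = _oracle_concentration(events, CL, V, times)[0]
            r = obs - f
            want += (r @ r) / p0.sigma_add**2 + len(obs) * (LOG_2PI + 2 * math.log(p0.sigma_add))
        assert marginal_ofv(small_dataset, p0) == pytest.approx(want, rel=1e-6)

    def test_sigma_zero_raises(self, small_dataset, pop):
        with pytest.raises(LikelihoodError):
            marginal_ofv(small_dataset, pop.replace(sigma_add=0.0))

    def test_true_beta_beats_no_covariate(self, small_dataset, pop):
        # data were generated with beta = 0.9; dropping the covariate must
        # cost far more than the chi-square threshold
        ofv_base = marginal_ofv(small_dataset, pop.replace(beta_GFR_CL=0.0))
        ofv_ext = marginal_ofv(small_dataset, pop)
        delta, significant = lrt_covariate(ofv_base, ofv_ext)
        assert significant
        assert delta > 3.84


class TestLrt:
    def test_threshold_is_strict(self):
        delta, sig = lrt_covariate(100.0, 96.16)
        assert delta == pytest.approx(3.84)
        assert not sig  # 3.84 does not strictly exceed 3.841...
        assert lrt_covariate(100.0, 96.0)[1]
        assert not lrt_covariate(100.0, 98.0)[1]

    def test_two_df(self):
        assert not lrt_covariate(100.0, 95.0, df=2)[1]  # threshold 5.99
        assert lrt_covariate(100.0, 93.0, df=2)[1]


class TestFit:
    def test_exact_recovery_without_variability(self, pop):
        # noise-free data from a fixed-effects model: the fit must recover
        # CL_pop, V_pop and beta essentially exactly (2-decimal DV rounding
        # is the only error source)
        truth = pop.replace(omega_CL=0.0, omega_V=0.0, sigma_add=0.0)
        cfg = CohortConfig(n_subjects=12, samples_per_subject_range=(4, 6), seed=31)
        dataset = generate_tdm_dataset(generate_cohort(cfg), truth, cfg)
        init = truth.replace(CL_pop=3.2, V_pop=60.0, beta_GFR_CL=0.5, sigma_add=0.1)
        settings = FitSettings(
            n_starts=1, fix={"omega_CL": 0.0, "omega_V": 0.0, "sigma_add": 0.1}
        )
        fit = fit_population(dataset, init=init, settings=settings)
        assert fit.estimates.CL_pop == pytest.approx(4.45, rel=0.005)
        assert fit.estimates.V_pop == pytest.approx(88.0, rel=0.005)
        assert fit.estimates.beta_GFR_CL == pytest.approx(0.9, abs=0.02)

    def test_fix_pins_parameters(self, small_dataset, pop):
        settings = FitSettings(n_starts=1, maxiter=40, fix={"beta_GFR_CL": 0.0})
        fit = fit_population(small_dataset, init=pop, settings=settings)
        assert fit.estimates.beta_GFR_CL == 0.0

    def test_fit_result_structure(self, small_fit, small_dataset, pop):
        assert set(small_fit.etas) == set(small_dataset.subject_ids())
        assert small_fit.n_evaluations > 0
        assert math.isfinite(small_fit.ofv)
        # the optimum cannot be worse than the (true-parameter) start
        assert small_fit.ofv <= marginal_ofv(small_dataset, pop) + 1e-6
        for name in ("CL_pop", "V_pop", "omega_CL", "omega_V", "sigma_add"):
            assert getattr(small_fit.estimates, name) > 0


class TestEmpiricalBayes:
    def _one_subject(self, pop, seed=3):
        cfg = CohortConfig(n_subjects=1, samples_per_subject_range=(6, 6), seed=seed)
        dataset = generate_tdm_dataset(generate_cohort(cfg), pop, cfg)
        return next(iter(dataset.subject_records()))

    def test_zero_omegas_return_prior_mode(self, pop):
        subject, regimen, times, obs = self._one_subject(pop)
        p0 = pop.replace(omega_CL=0.0, omega_V=0.0)
        assert empirical_bayes(regimen, times, obs, subject, p0) == RandomEffects(0.0, 0.0)

    def test_no_observations_return_prior_mode(self, pop):
        subject, regimen, _, _ = self._one_subject(pop)
        assert empirical_bayes(regimen, [], [], subject, pop) == RandomEffects(0.0, 0.0)

    def test_tighter_prior_shrinks_prior_quadratic_form(self, pop):
        # uniformly scaling both omegas down scales the prior penalty
        # q(eta) = (eta_CL/w1)^2 + (eta_V/w2)^2 up, so the MAP's q must not
        # increase (individual components may trade off against each other)
        subject, regimen, times, obs = self._one_subject(pop)

        def q(etas):
            return (etas.eta_CL / pop.omega_CL) ** 2 + (etas.eta_V / pop.omega_V) ** 2

        loose = empirical_bayes(regimen, times, obs, subject, pop)
        tight = empirical_bayes(
            regimen, times, obs, subject,
            pop.replace(omega_CL=0.1 * pop.omega_CL, omega_V=0.1 * pop.omega_V),
        )
        assert q(tight) <= q(loose) + 1e-9


class TestShrinkage:
    def test_collapsed_etas_shrinkage_one(self):
        assert shrinkage([0.0, 0.0, 0.0], 0.46) == pytest.approx(1.0)

    def test_full_spread_shrinkage_zero(self):
        rng = np.random.default_rng(0)
        etas = 0.46 * rng.standard_normal(20000)
        assert shrinkage(etas, 0.46) == pytest.approx(0.0, abs=0.02)

    def test_undefined_for_zero_omega(self):
        assert math.isnan(shrinkage([0.1, -0.2], 0.0))

    def test_sparse_design_shrinks_more_than_rich(self, pop):
        # EBEs computed under the true population: one sample per subject
        # pins the individual far less than nine, so eta_V collapses more
        out = {}
        for label, rng_ in (("sparse", (1, 1)), ("rich", (9, 9))):
            cfg = CohortConfig(n_subjects=25, samples_per_subject_range=rng_, seed=17)
            dataset = generate_tdm_dataset(generate_cohort(cfg), pop, cfg)
            etas_v = [
                empirical_bayes(reg, t, y, s, pop).eta_V
                for s, reg, t, y in dataset.subject_records()
            ]
            out[label] = shrinkage(etas_v, pop.omega_V)
        assert out["sparse"] > out["rich"]
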