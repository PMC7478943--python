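import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import norm

from mctmm.cohort import CohortDesign, generate_cohort
from mctmm.data import PatientRecord, pack
from mctmm.estimation import (
    bootstrap,
    fit,
    individual_loglik,
    likelihood_ratio_test,
    marginal_ofv,
)
from mctmm.likelihood import (
    agq_subject_loglik,
    laplace_subject_loglik,
    population_loglik,
)
from mctmm.markov import build_generator
from mctmm.model_core import (
    CovariateVector,
    EtaPair,
    PopulationParams,
    cumulative_logits,
    grade_distribution,
    individual_met,
)

SEED = 12345


def _direct_loglik(record, params, eta, spec):
    """Oracle: per-interval products of scipy matrix exponentials."""
    total = 0.0
    prev_t, prev_g = 0, 0
    for t, g in zip(record.times.astype(int), record.grades):
        tmat = np.eye(4)
        for c in range(prev_t + 1, t + 1):
            cov = CovariateVector(daily_dose=record.cycle_doses[c - 1])
            target = grade_distribution(
                cumulative_logits(params, eta, cov, spec))
            gen = build_generator(target, individual_met(params, eta, cov, spec))
            tmat = tmat @ expm(gen.q)
        total += np.log(tmat[prev_g, g])
        prev_t, prev_g = t, g
    return total


class TestIndividualLoglik:
    def test_matches_matrix_exponential_oracle(self, reference_params,
                                               final_spec):
        rec = PatientRecord("p", [1, 2, 3, 5], [0, 1, 2, 2],
                            [4000, 4000, 3000, 0, 0])
        eta = EtaPair(0.4, -0.3)
        ll = individual_loglik(rec, reference_params, eta, final_spec)
        want = _direct_loglik(rec, reference_params, eta, final_spec)
        assert abs(ll - want) < 1e-10

    def test_additive_over_subjects(self, reference_params, final_spec):
        rec = PatientRecord("p", [1, 2], [1, 2], [3000, 3000])
        single = individual_loglik(rec, reference_params, EtaPair(), final_spec)
        packed = pack([rec, rec])
        both = population_loglik(packed, reference_params, final_spec,
                                 np.zeros(2), np.zeros(2))
        assert abs(both.sum() - 2 * single) < 1e-12

    def test_frozen_dynamics_keeps_baseline(self, final_spec):
        slow = PopulationParams(alpha1=1.81, b2=-1.8, b3=-2.08, met=1e9)
        rec = PatientRecord("p", [1], [0], [3000])
        ll = individual_loglik(rec, slow, EtaPair(), final_spec)
        assert abs(ll) < 1e-8  # P(stay grade 0) ~ 1


class TestMarginalOfv:
    def test_zero_variance_equals_conditional(self, small_cohort, final_spec):
        params = PopulationParams(alpha1=1.81, b2=-1.8, b3=-2.08, met=1.09,
                                  theta_dose=8.33e-4)
        ofv = marginal_ofv(small_cohort, params, final_spec)
        cond = sum(individual_loglik(r, params, EtaPair(), final_spec)
                   for r in small_cohort)
        assert abs(ofv - (-2 * cond)) < 1e-9

    def test_empty_subject_does_not_change_ofv(self, small_cohort,
                                               reference_params, final_spec):
        ofv = marginal_ofv(small_cohort, reference_params, final_spec)
        extra = small_cohort + [PatientRecord("empty", [], [], [])]
        assert abs(marginal_ofv(extra, reference_params, final_spec)
                   - ofv) < 1e-9

    def test_unknown_method_rejected(self, small_cohort, reference_params):
        with pytest.raises(ValueError):
            marginal_ofv(small_cohort, reference_params, method="focei")


class TestLaplaceAndQuadrature:
    def test_agq_matches_dense_grid(self, reference_params, final_spec):
        # brute-force 2-D trapezoid integration as the independent oracle
        rec = PatientRecord("p", [1, 2, 3], [0, 2, 1], [3500, 3500, 3500])
        packed = pack([rec])
        om = np.array([reference_params.omega_alpha,
                       reference_params.omega_met])
        xs = np.linspace(-6, 6, 201) * om[0]
        ys = np.linspace(-6, 6, 201) * om[1]
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        ll = population_loglik(packed, reference_params, final_spec,
                               xx.reshape(-1, 1), yy.reshape(-1, 1))[:, 0]
        logphi = (norm.logpdf(xx.ravel(), 0, om[0])
                  + norm.logpdf(yy.ravel(), 0, om[1]))
        from scipy.special import logsumexp
        grid = logsumexp(ll + logphi) + np.log(
            (xs[1] - xs[0]) * (ys[1] - ys[0]))
        agq = agq_subject_loglik(packed, reference_params, final_spec)[0]
        assert abs(agq - grid) < 1e-5

    def test_laplace_matches_reference_construction(self, reference_params,
                                                    final_spec):
        # independent mode search (Nelder-Mead) + FD Hessian, then the
        # closed-form Laplace expression
        from scipy.optimize import minimize
        rec = PatientRecord("p", [1, 2, 3], [1, 1, 2], [2500, 2500, 2500])
        packed = pack([rec])
        om = np.array([reference_params.omega_alpha,
                       reference_params.omega_met])

        def f(e):
            ll = population_loglik(packed, reference_params, final_spec,
                                   np.array([e[0]]), np.array([e[1]]))[0]
            return -ll + 0.5 * np.sum(e ** 2 / om ** 2)

        res = minimize(f, [0, 0], method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-14))
        h = 1e-5
        hess = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                ei = np.eye(2)[i] * h
                ej = np.eye(2)[j] * h
                hess[i, j] = (f(res.x + ei + ej) - f(res.x + ei - ej)
                              - f(res.x - ei + ej)
                              + f(res.x - ei - ej)) / (4 * h * h)
        want = (-res.fun - np.sum(np.log(om))
                - 0.5 * np.log(np.linalg.det(hess)))
        got, mode = laplace_subject_loglik(packed, reference_params,
                                           final_spec)
        assert abs(got[0] - want) < 1e-4
        np.testing.assert_allclose(mode[0], res.x, atol=1e-4)

    def test_one_dimensional_random_effect(self, small_cohort, final_spec):
        # omega_met = 0 reduces the integral to one dimension
        params = PopulationParams(alpha1=1.81, b2=-1.8, b3=-2.08, met=1.09,
                                  theta_dose=8.33e-4, omega_alpha=1.12,
                                  omega_met=0.0)
        lap = marginal_ofv(small_cohort, params, final_spec, "laplace")
        agq = marginal_ofv(small_cohort, params, final_spec, "agq")
        assert np.isfinite(lap) and np.isfinite(agq)
        # same ballpark; the residual gap is the Laplace approximation
        # error in the skewed intercept dimension, not a code defect
        assert abs(lap - agq) < 0.15 * len(small_cohort)


class TestLikelihoodRatioTest:
    def test_dose_effect_call(self):
        dec = likelihood_ratio_test(0.0, -23.45, df=1)
        assert dec.p_value < 1e-5
        assert dec.significant

    def test_sex_effect_call(self):
        dec = likelihood_ratio_test(0.0, -3.454, df=1)
        assert abs(dec.p_value - 0.063) < 5e-3
        assert not dec.significant

    def test_no_improvement(self):
        dec = likelihood_ratio_test(100.0, 100.0, df=1)
        assert dec.p_value == 1.0
        assert not dec.significant

    def test_threshold_is_chi2_99(self):
        just_under = likelihood_ratio_test(0.0, -6.62, df=1)
        just_over = likelihood_ratio_test(0.0, -6.64, df=1)
        assert not just_under.significant
        assert just_over.significant

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(0.0, -5.0, df=3)


@pytest.fixture(scope="module")
def tiny_fit(reference_params, final_spec):
    """Refit from the truth on a 15-subject cohort (shared, ~1 min)."""
    cohort = generate_cohort(CohortDesign.scaled(15), reference_params,
                             final_spec, np.random.default_rng(SEED))
    result = fit(cohort, reference_params, final_spec, compute_se=True,
                 maxiter=60)
    return cohort, result


class TestFit:
    def test_refit_from_truth_does_not_worsen(self, tiny_fit,
                                              reference_params, final_spec):
        cohort, result = tiny_fit
        ofv_truth = marginal_ofv(cohort, reference_params, final_spec)
        assert result.ofv <= ofv_truth + 1e-6

    def test_estimates_respect_constraints(self, tiny_fit):
        _, result = tiny_fit
        e = result.estimates
        assert e.b2 < 0 and e.b3 < 0 and e.met > 0
        assert e.omega_alpha >= 0 and e.omega_met >= 0

    def test_standard_errors_reported(self, tiny_fit):
        _, result = tiny_fit
        assert set(result.standard_errors) == {
            "alpha1", "b2", "b3", "met", "theta_dose",
            "omega_alpha", "omega_met"}
        table = result.parameter_table()
        assert len(table) == 7
        assert np.isfinite(result.ofv)

    def test_ordering_invariance(self, small_cohort, reference_params,
                                 final_spec):
        ofv = marginal_ofv(small_cohort, reference_params, final_spec)
        ofv_rev = marginal_ofv(small_cohort[::-1], reference_params,
                               final_spec)
        assert abs(ofv - ofv_rev) < 1e-8


class TestBootstrap:
    def test_identity_replicate_matches_refit(self, tiny_fit, final_spec):
        cohort, result = tiny_fit
        boot = bootstrap(cohort, result.estimates, final_spec,
                         n_replicates=1, seed=SEED, maxiter=60)
        assert boot.n_failed == 0
        assert boot.n_replicates == 1
        # with one replicate the median IS that replicate's estimate
        assert boot.medians["met"] == pytest.approx(
            boot.estimates["met"].iloc[0])
        assert boot.ci_lower["met"] <= boot.medians["met"] <= boot.ci_upper["met"]

    def test_invalid_replicate_count(self, small_cohort, reference_params):
        with pytest.raises(ValueError):
            bootstrap(small_cohort, reference_params, n_replicates=0)
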