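import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm, null_space

from mctmm.markov import (
    build_generator,
    generators_batch,
    interval_transition_matrix,
    propagate,
    transition_matrices_batch,
    transition_matrix,
)
from mctmm.model_core import (
    CovariateVector,
    EtaPair,
    cumulative_logits,
    grade_distribution,
)


def target_strategy():
    """Grade distributions bounded away from degeneracy."""
    return st.lists(st.floats(0.05, 1.0), min_size=4, max_size=4).map(
        lambda w: np.asarray(w) / np.sum(w))


class TestBuildGenerator:
    def test_uniform_target_unit_met(self):
        # symmetric case: each adjacent rate is half the pair rate 1/MET
        gen = build_generator(np.full(4, 0.25), met_i=1.0)
        adjacent = [gen.q[i, j] for i in range(4) for j in range(4)
                    if abs(i - j) == 1]
        np.testing.assert_allclose(adjacent, 0.5)

    @given(p=target_strategy(), met=st.floats(0.05, 10))
    def test_adjacent_pair_rates_sum_to_met_inverse(self, p, met):
        # the property that makes MET the mean equilibration time
        q = build_generator(p, met).q
        for i in range(3):
            np.testing.assert_allclose(q[i, i + 1] + q[i + 1, i], 1.0 / met,
                                       rtol=1e-12)

    @given(p=target_strategy(), met=st.floats(0.05, 10))
    def test_structure_and_detailed_balance(self, p, met):
        gen = build_generator(p, met)
        q = gen.q
        # tridiagonal, off-diagonals non-negative, zero row sums
        for i in range(4):
            for j in range(4):
                if abs(i - j) > 1:
                    assert q[i, j] == 0.0
                elif i != j:
                    assert q[i, j] >= 0.0
        np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)
        # detailed balance pi_i K(i->j) = pi_j K(j->i) to machine precision
        for i in range(3):
            np.testing.assert_allclose(p[i] * q[i, i + 1],
                                       p[i + 1] * q[i + 1, i], rtol=1e-15)

    def test_met_rescales_all_rates(self):
        p = np.array([0.4, 0.3, 0.2, 0.1])
        q1 = build_generator(p, 1.0).q
        q2 = build_generator(p, 2.0).q
        np.testing.assert_allclose(q2, q1 / 2.0, atol=1e-15)

    def test_stationary_distribution_is_target(self, reference_params):
        # null-space oracle: the left null vector of Q equals the
        # proportional-odds distribution the generator was built from
        target = grade_distribution(cumulative_logits(reference_params)).p
        gen = build_generator(target, reference_params.met)
        ns = null_space(gen.q.T)
        assert ns.shape[1] == 1
        pi = ns[:, 0] / ns[:, 0].sum()
        np.testing.assert_allclose(pi, target, atol=1e-10)

    def test_nonpositive_met_rejected(self):
        with pytest.raises(ValueError):
            build_generator(np.full(4, 0.25), 0.0)


class TestPropagate:
    def test_zero_elapsed_is_indicator(self):
        gen = build_generator(np.array([0.4, 0.3, 0.2, 0.1]), 1.0)
        for g in range(4):
            dist = propagate(gen, g, 0.0)
            np.testing.assert_allclose(dist.p, np.eye(4)[g], atol=1e-14)

    def test_ergodic_limit_is_stationary(self):
        target = np.array([0.35, 0.3, 0.25, 0.1])
        gen = build_generator(target, 1.3)
        for g in range(4):
            dist = propagate(gen, g, 1000.0)
            np.testing.assert_allclose(dist.p, target, atol=1e-8)

    @pytest.mark.parametrize("daily_dose", [0.0, 3000.0, 5000.0])
    def test_matches_ode_integration(self, reference_params, daily_dose):
        # independent oracle: high-accuracy ODE solve of the probability
        # balance equations (adjacent-state gains and losses)
        logits = cumulative_logits(
            reference_params, cov=CovariateVector(daily_dose=daily_dose))
        target = grade_distribution(logits)
        gen = build_generator(target, reference_params.met)
        q = gen.q

        def rhs(_, y):
            return y @ q

        for g in range(4):
            sol = solve_ivp(rhs, (0.0, 1.0), np.eye(4)[g], rtol=1e-10,
                            atol=1e-12, dense_output=False)
            dist = propagate(gen, g, 1.0)
            np.testing.assert_allclose(dist.p, sol.y[:, -1], atol=1e-8)

    def test_negative_elapsed_rejected(self):
        gen = build_generator(np.full(4, 0.25), 1.0)
        with pytest.raises(ValueError):
            propagate(gen, 0, -1.0)


class TestTransitionMatrix:
    def test_rows_are_distributions(self, reference_params):
        tm = transition_matrix(reference_params, EtaPair(0.3, -0.2), 4000.0)
        assert np.all(tm.t_mat >= 0) and np.all(tm.t_mat <= 1)
        np.testing.assert_allclose(tm.t_mat.sum(axis=1), 1.0, atol=1e-10)

    def test_frozen_dynamics_for_large_met(self, reference_params):
        slow = reference_params.replace(met=1e9)
        tm = transition_matrix(slow, daily_dose=3000.0, elapsed=1.0)
        np.testing.assert_allclose(tm.t_mat, np.eye(4), atol=1e-8)

    def test_instant_equilibration_for_small_met(self, reference_params):
        fast = reference_params.replace(met=1e-4)
        target = grade_distribution(cumulative_logits(reference_params)).p
        tm = transition_matrix(fast, daily_dose=3000.0, elapsed=1.0)
        for g in range(4):
            np.testing.assert_allclose(tm.t_mat[g], target, atol=1e-8)

    def test_short_time_excludes_nonadjacent_jumps(self, reference_params):
        # P(i -> j)/dt vanishes as dt -> 0 for |i-j| > 1 (two jumps needed)
        for dt in (1e-3, 1e-4):
            tm = transition_matrix(reference_params, daily_dose=3000.0,
                                   elapsed=dt)
            for i in range(4):
                for j in range(4):
                    if abs(i - j) > 1:
                        assert tm.t_mat[i, j] / dt < 10 * dt

    @given(p=target_strategy(), met=st.floats(0.2, 5),
           a=st.floats(0.1, 2), b=st.floats(0.1, 2))
    def test_chapman_kolmogorov(self, p, met, a, b):
        gen = build_generator(p, met)
        ta = expm(gen.q * a)
        tb = expm(gen.q * b)
        tab = expm(gen.q * (a + b))
        np.testing.assert_allclose(ta @ tb, tab, atol=1e-9)

    def test_piecewise_interval_matches_product(self, reference_params):
        eta = EtaPair(0.2, 0.1)
        t1 = transition_matrix(reference_params, eta, 4000.0).t_mat
        t2 = transition_matrix(reference_params, eta, 0.0).t_mat
        tm = interval_transition_matrix(reference_params, eta, [4000.0, 0.0])
        np.testing.assert_allclose(tm.t_mat, t1 @ t2, atol=1e-12)
        assert tm.elapsed == 2.0


class TestBatchedKernel:
    def test_matches_scipy_expm(self):
        rng = np.random.default_rng(1)
        p = np.maximum(rng.dirichlet(np.ones(4), size=300), 1e-12)
        met = np.exp(rng.normal(0, 1, 300))
        el = rng.uniform(0.1, 3, 300)
        t_fast = transition_matrices_batch(p, met, el)
        q = generators_batch(p, met)
        t_ref = expm(q * el[:, None, None])
        np.testing.assert_allclose(t_fast, t_ref, atol=1e-11)

    def test_handles_floored_probabilities(self):
        p = np.array([[1 - 3e-12, 1e-12, 1e-12, 1e-12],
                      [1e-12, 1e-12, 0.5, 0.5 - 2e-12]])
        t = transition_matrices_batch(p, np.array([1.0, 0.5]), 1.0)
        assert np.all(np.isfinite(t))
        np.testing.assert_allclose(t.sum(axis=-1), 1.0, atol=1e-10)
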