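import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bvcsr
from bvcsr import SuccessorMatrix, RewardWeights


def ring_walk_sr(n_states=5, gamma=0.9, alpha0=0.1, tau=1000.0,
                 n_updates=100_000, seed=0):
    """TD-learn the SR of a symmetric random walk on a ring with one-hot
    features; the tabular SR (I - gamma P)^-1 is the analytic target.

    A Robbins-Monro schedule alpha_t = alpha0 / (1 + t/tau) drives the
    stochastic iterates to the fixed point instead of a noise ball.
    """
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    P = np.zeros((n_states, n_states))
    for s in range(n_states):
        P[s, (s - 1) % n_states] = 0.5
        P[s, (s + 1) % n_states] = 0.5
    sm = SuccessorMatrix(np.eye(n_states), gamma=gamma, alpha_M=alpha0)
    eye = np.eye(n_states)
    s = 0
    for t in range(n_updates):
        sm = replace(sm, alpha_M=alpha0 / (1 + t / tau))
        s2 = (s + rng.choice([-1, 1])) % n_states
        sm = bvcsr.td_update(sm, eye[s], eye[s2])
        s = s2
    target = np.linalg.inv(np.eye(n_states) - gamma * P)
    return sm.M, target


class TestSuccessorFeatures:
    def test_identity_matrix_returns_features(self):
        sm = SuccessorMatrix(np.eye(4))
        f = np.array([1.0, 2.0, 0.0, 0.5])
        np.testing.assert_array_equal(bvcsr.successor_features(sm, f), f)

    def test_zero_features_give_zero(self):
        sm = SuccessorMatrix(np.arange(9.0).reshape(3, 3))
        np.testing.assert_array_equal(
            bvcsr.successor_features(sm, np.zeros(3)), np.zeros(3)
        )

    def test_matches_elementwise_dot_product(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(4, 4))
        f = rng.normal(size=4)
        psi = bvcsr.successor_features(SuccessorMatrix(M), f)
        expected = [sum(M[i, j] * f[j] for j in range(4)) for i in range(4)]
        np.testing.assert_allclose(psi, expected)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            bvcsr.successor_features(SuccessorMatrix(np.eye(3)), np.ones(4))


class TestTdUpdate:
    def test_zero_feature_leaves_m_unchanged(self):
        sm = SuccessorMatrix(np.full((3, 3), 0.7))
        out = bvcsr.td_update(sm, np.zeros(3), np.ones(3))
        np.testing.assert_array_equal(out.M, sm.M)

    def test_single_update_closed_form(self):
        """From M=0 with alpha=1, gamma=0, a one-hot transition writes e1 e1^T."""
        sm = SuccessorMatrix(np.zeros((3, 3)), gamma=0.0, alpha_M=1.0)
        e1 = np.array([1.0, 0.0, 0.0])
        out = bvcsr.td_update(sm, e1, np.array([0.0, 1.0, 0.0]))
        np.testing.assert_array_equal(out.M, np.outer(e1, e1))

    def test_fixed_point_invariance(self):
        """No update when f_t + gamma psi_next - psi_t = 0."""
        rng = np.random.default_rng(2)
        M = rng.normal(size=(3, 3))
        sm = SuccessorMatrix(M, gamma=0.5)
        f_t = rng.uniform(0.1, 1.0, 3)
        # choose f_next solving M f_next = (M f_t - f_t) / gamma
        f_next = np.linalg.solve(M, (M @ f_t - f_t) / 0.5)
        out = bvcsr.td_update(sm, f_t, f_next)
        np.testing.assert_allclose(out.M, sm.M, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.001, 0.5))
    def test_update_linear_in_learning_rate(self, seed, alpha):
        rng = np.random.default_rng(seed)
        M = rng.normal(size=(3, 3))
        f_t, f_next = rng.uniform(0, 1, 3), rng.uniform(0, 1, 3)
        d1 = bvcsr.td_update(SuccessorMatrix(M, alpha_M=1.0), f_t, f_next).M - M
        da = bvcsr.td_update(SuccessorMatrix(M, alpha_M=alpha), f_t, f_next).M - M
        np.testing.assert_allclose(da, alpha * d1, rtol=1e-9, atol=1e-12)

    def test_ring_converges_to_tabular_sr(self):
        M, target = ring_walk_sr(n_updates=30_000)
        assert np.max(np.abs(M - target) / np.abs(target)) < 0.04


class TestRewardAndValue:
    def test_no_reward_keeps_weights_zero(self):
        rw = RewardWeights(np.zeros(4))
        psi = np.random.default_rng(0).uniform(0, 1, 4)
        out = bvcsr.reward_update(rw, psi, psi, 0.0, 0.99)
        np.testing.assert_array_equal(out.R, np.zeros(4))

    def test_consistent_weights_are_fixed_point(self):
        # single state, gamma=0: delta = r - psi.R; choose R with psi.R = r
        rw = RewardWeights(np.array([2.0]), alpha_R=1.0)
        out = bvcsr.reward_update(rw, np.array([1.0]), np.array([1.0]), 2.0, 0.0)
        np.testing.assert_array_equal(out.R, rw.R)

    def test_scalar_one_shot_learning(self):
        rw = RewardWeights(np.array([0.0]), alpha_R=1.0)
        out = bvcsr.reward_update(rw, np.array([1.0]), np.array([1.0]), 3.0, 0.0)
        assert out.R[0] == pytest.approx(3.0)

    def test_value_basis_and_linearity(self):
        rng = np.random.default_rng(4)
        R = RewardWeights(rng.normal(size=5))
        e2 = np.eye(5)[2]
        assert bvcsr.value(e2, R) == pytest.approx(R.R[2])
        psi = rng.normal(size=5)
        assert bvcsr.value(psi, R) == pytest.approx(float(np.dot(psi, R.R)))
        assert bvcsr.value(2 * psi, R) == pytest.approx(2 * bvcsr.value(psi, R))


class TestLearnSr:
    def test_short_trajectory_returns_m0(self, small_fmap):
        traj = bvcsr.Trajectory(
            t=np.array([0.0]), x=np.array([0.5]), y=np.array([0.5]),
            heading=np.array([0.0]),
        )
        m0 = bvcsr.SuccessorMatrix.identity(small_fmap.n)
        out = bvcsr.learn_sr(small_fmap, traj, M0=m0)
        np.testing.assert_array_equal(out.M, m0.M)

    def test_order_dependence(self, small_fmap):
        """The SR is policy dependent: a reversed path learns a different M."""
        t = np.arange(400) * 0.02
        x = np.linspace(0.1, 0.9, 400)
        y = np.full(400, 0.3)
        fwd = bvcsr.Trajectory(t=t, x=x, y=y, heading=np.zeros(400))
        rev = bvcsr.Trajectory(t=t, x=x[::-1], y=y, heading=np.zeros(400))
        Mf = bvcsr.learn_sr(small_fmap, fwd).M
        Mr = bvcsr.learn_sr(small_fmap, rev).M
        assert not np.allclose(Mf, Mr)

    def test_overlapping_cells_develop_stronger_weights(self, small_fmap, small_learned):
        """After foraging, BVC pairs with overlapping fields carry larger SR
        weights than pairs with disjoint fields."""
        _, sm = small_learned
        F = small_fmap.matrix()
        overlap = F.T @ F
        n = small_fmap.n
        iu = np.triu_indices(n, k=1)
        ov = overlap[iu]
        w = ((sm.M + sm.M.T) / 2)[iu]
        hi = w[ov > np.quantile(ov, 0.9)]
        lo = w[ov < np.quantile(ov, 0.1)]
        assert hi.mean() > lo.mean()

    def test_update_count_logged(self, small_fmap):
        traj = bvcsr.simulate_trajectory(small_fmap.env, 10.0, seed=9)
        out = bvcsr.learn_sr(small_fmap, traj)
        assert out.updates == len(traj) - 1
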