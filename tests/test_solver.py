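"""Solver: classical reduction against textbook recursions, descent,
feedforward structure, decoupling and determinism."""
from dataclasses import replace

import numpy as np
import pytest

from visreach.task import NoiseSpec, CostSpec, make_experiment
from visreach.solver import (ControlLaw, SolverSettings, solve, kalman_pass,
                             expected_cost, classical_init,
                             decompose_controller, _forward)
from conftest import classical_noise


def lqr_oracle(cfg):
    """Independent textbook finite-horizon LQR backward recursion."""
    A, B = cfg.plant.A, cfg.plant.B
    Qn, R = cfg.cost.Qn, cfg.cost.R
    n = cfg.plant.n
    S = Qn.copy()
    L = np.zeros((n - 1, 2, 10))
    for t in range(n - 2, -1, -1):
        L[t] = np.linalg.inv(R + B.T @ S @ B) @ B.T @ S @ A
        Ac = A - B @ L[t]
        S = Qn * 0 + A.T @ S @ Ac          # Q = 0
        S = 0.5 * (S + S.T)
    return L


def kalman_oracle(cfg):
    """Independent textbook discrete Kalman recursion (predictive form)."""
    A, H = cfg.plant.A, cfg.plant.H
    W = np.diag(cfg.noise.omega_w)
    Oxi = np.diag(cfg.noise.omega_xi)
    n = cfg.plant.n
    Se = cfg.Sigma1()
    K = np.zeros((n - 1, 10, 6))
    for t in range(n - 1):
        K[t] = A @ Se @ H.T @ np.linalg.inv(H @ Se @ H.T + W)
        Se = (A - K[t] @ H) @ Se @ (A - K[t] @ H).T + Oxi + K[t] @ W @ K[t].T
        Se = 0.5 * (Se + Se.T)
    return K


class TestClassicalReduction:
    """With sigma_f = sigma_g = a = 0 (and no internal noise) the separation
    principle holds and the solver must coincide with LQR + Kalman."""

    def test_gains_match_oracles(self, cfg_classical, law_classical):
        assert np.abs(law_classical.L - lqr_oracle(cfg_classical)).max() < 1e-8
        assert np.abs(law_classical.K - kalman_oracle(cfg_classical)).max() < 1e-8

    def test_feedforward_identically_zero(self, law_classical):
        assert np.abs(law_classical.l).max() < 1e-10

    def test_converges_immediately(self, law_classical):
        # classical init is already the fixed point: one descent iteration
        # changes nothing beyond the initial evaluation
        assert law_classical.converged
        assert len(law_classical.cost_history) <= 3


class TestDescentAndOptimality:
    def test_cost_history_non_increasing(self, law_orth, law_opp):
        for law in (law_orth, law_opp):
            h = np.asarray(law.cost_history)
            assert np.all(np.diff(h) <= 1e-9 * np.abs(h[:-1]))

    def test_zero_init_reaches_similar_cost(self, cfg_orth, law_orth):
        law0 = solve(cfg_orth, SolverSettings(init_mode="zero"))
        assert law0.expected_cost <= 1.05 * law_orth.expected_cost

    def test_local_optimality_random_perturbations(self, cfg_orth, law_orth):
        rng = np.random.default_rng(11)
        J0 = expected_cost(law_orth, cfg_orth)
        base = np.sqrt((law_orth.L ** 2).sum() + (law_orth.l ** 2).sum())
        for _ in range(30):
            dL = rng.standard_normal(law_orth.L.shape)
            dl = rng.standard_normal(law_orth.l.shape)
            nrm = np.sqrt((dL ** 2).sum() + (dl ** 2).sum())
            pert = ControlLaw(L=law_orth.L + 1e-3 * base * dL / nrm,
                              l=law_orth.l + 1e-3 * base * dl / nrm,
                              K=law_orth.K)
            assert expected_cost(pert, cfg_orth) >= J0 - 1e-6 * J0

    def test_deterministic_bitwise(self, cfg_orth, law_orth):
        law2 = solve(cfg_orth)
        assert np.array_equal(law2.L, law_orth.L)
        assert np.array_equal(law2.l, law_orth.l)
        assert np.array_equal(law2.K, law_orth.K)


class TestKalmanPass:
    def test_gain_shrinks_with_observation_noise(self, cfg_classical):
        law = classical_init(cfg_classical)
        K1, _ = kalman_pass(law, cfg_classical)
        noisy = replace(cfg_classical, noise=classical_noise(omega_w=1e-2))
        K2, _ = kalman_pass(classical_init(noisy), noisy)
        f1 = np.linalg.norm(K1, axis=(1, 2))
        f2 = np.linalg.norm(K2, axis=(1, 2))
        assert np.all(f2 < f1)

    def test_switching_above_threshold(self, cfg_orth):
        """With a high sensitivity the mean v_theta crosses a/kappa and the
        state-dependent observation noise drops out entirely."""
        fast = replace(make_experiment("exp1", kappa=8.0).single(6))
        law = solve(fast)
        _, track = kalman_pass(law, fast)
        assert track.switched.any()
        assert np.all(track.s2[track.switched] == 0.0)
        # in the switched (fully visible) regime the innovation variance on
        # the position channels is at the omega_w floor
        t_sw = int(np.flatnonzero(track.switched)[0])
        N = (fast.plant.H @ track.SigmaE[t_sw] @ fast.plant.H.T
             + np.diag(fast.noise.omega_w + fast.noise.sigma_g * track.s2[t_sw]))
        state_dep = fast.noise.sigma_g[0] * track.s2[t_sw]
        assert state_dep == 0.0
        assert N[0, 0] <= track.SigmaE[t_sw][0, 0] + fast.noise.omega_w[0] + 1e-15

    def test_estimator_unbiased_in_moments(self, cfg_orth, law_orth):
        _, track = _forward(law_orth.L, law_orth.l, law_orth.K, cfg_orth,
                            compute_K=False)
        # moment propagation keeps mean state and mean estimate identical;
        # covariances stay PSD
        for t in range(0, cfg_orth.plant.n, 10):
            for M in (track.SigmaX[t], track.SigmaHat[t], track.SigmaE[t]):
                assert np.linalg.eigvalsh(M).min() >= -1e-10


class TestFeedforward:
    def test_nonzero_with_state_dependent_noise(self, law_orth):
        """Target orthogonal to theta: the optimal law has a significant
        feedforward component."""
        assert np.abs(law_orth.l).max() > 1e-3

    def test_orthogonal_channel_zero(self, law_orth, cfg_orth):
        rep = decompose_controller(law_orth, cfg_orth.field)
        assert np.abs(rep.l_orthogonal).max() <= 1e-8 * np.abs(rep.l_rot).max()

    def test_rotation_equivariance_of_decomposition(self):
        """Rotating the whole problem by 90 deg leaves the decomposition
        invariant up to axis relabeling."""
        cfg0 = make_experiment("exp1", theta=0.0).single(9)
        cfg90 = make_experiment("exp1", theta=90.0).single(0)  # start rotated too
        rep0 = decompose_controller(solve(cfg0), cfg0.field)
        rep90 = decompose_controller(solve(cfg90), cfg90.field)
        assert np.allclose(rep0.l_parallel, rep90.l_parallel, atol=1e-8)
        assert np.allclose(rep0.L_rot, rep90.L_rot, atol=1e-7)


class TestExpectedCost:
    def test_zero_at_goal(self):
        cfg = make_experiment("exp1").single(0)
        cfg = replace(cfg, starts=cfg.target[None], sigma1_pos=0.0,
                      noise=NoiseSpec(sigma_f=0, sigma_g=np.zeros(6), a=0,
                                      omega_eta=np.zeros(10),
                                      omega_w=np.zeros(6)))
        n = cfg.plant.n
        zero_law = ControlLaw(L=np.zeros((n - 1, 2, 10)),
                              l=np.zeros((n - 1, 2)),
                              K=np.zeros((n - 1, 10, 6)))
        assert expected_cost(zero_law, cfg) == pytest.approx(0.0, abs=1e-20)

    def test_increases_with_position_weight(self, cfg_orth, law_orth):
        heavier = replace(cfg_orth, cost=CostSpec(
            w_pos=2 * cfg_orth.cost.w_pos, w_vel=cfg_orth.cost.w_vel,
            w_force=cfg_orth.cost.w_force))
        assert expected_cost(law_orth, heavier) > expected_cost(law_orth, cfg_orth)

    def test_nonnegative(self, law_orth, cfg_orth):
        assert expected_cost(law_orth, cfg_orth) >= 0.0


def test_mirror_symmetry_of_mean_trajectories():
    """Targets mirrored about the theta axis produce reflected mean paths."""
    cfg_up = make_experiment("exp1").single(3)     # start at 90 deg
    cfg_dn = make_experiment("exp1").single(9)     # start at 270 deg
    _, tr_up = _forward(*_law_tuple(solve(cfg_up)), cfg_up, compute_K=False)
    _, tr_dn = _forward(*_law_tuple(solve(cfg_dn)), cfg_dn, compute_K=False)
    flip = np.array([1, -1])
    assert np.abs(tr_up.mu[:, :2] - tr_dn.mu[:, :2] * flip).max() < 1e-6


def _law_tuple(law):
    return law.L, law.l, law.K
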