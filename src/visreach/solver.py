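"""Optimal affine controller and state estimator under signal-dependent motor
noise and affine state-dependent sensory noise.

The classical LQG separation principle fails here: the quality of sensory
feedback depends on the executed movement (observation noise scales with
a - kappa*v_theta), and motor noise scales with the control. The solver
therefore alternates two passes until the expected cost converges:

* ``kalman_pass`` -- forward propagation of the exact joint first/second
  moments of (x, x-hat) under the current control law, choosing at each step
  the filter gain K_t that minimizes the expected squared estimation error
  given the state-dependent observation covariance.
* ``control_pass`` -- backward sweep computing the affine law
  u_t = -L_t x-hat_t - l_t.  Each (L_t, l_t) is the exact minimizer of the
  total expected cost over that block, given K and all other gains: the
  cost-to-go is propagated as a quadratic-plus-linear function of the joint
  vector z = [x; x-hat] (the affine observation-noise term generates the
  linear part and hence the feedforward component l_t), and the minimization
  uses the forward moments, so the sweep is exact block-coordinate descent.

The affine/constant switching of the observation noise (the scale is clamped
to zero once a - kappa*v_theta <= 0, "fully detectable") is resolved against
the mean trajectory of the previous iterate, keeping each iteration's
subproblem linear-quadratic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import logging
import warnings

import numpy as np

from .task import NX, NU, NY, ExperimentConfig, InvalidParameterError

__all__ = ["ControlLaw", "MomentTrack", "SolverSettings", "DecompositionReport",
           "kalman_pass", "control_pass", "solve", "expected_cost",
           "decompose_controller", "classical_init"]

logger = logging.getLogger(__name__)


@dataclass
class ControlLaw:
    """Time-indexed affine control law and filter gains.

    L : (n-1, 2, 10) feedback gains; l : (n-1, 2) feedforward terms;
    K : (n-1, 10, 6) Kalman gains.
    """
    L: np.ndarray
    l: np.ndarray
    K: np.ndarray
    expected_cost: float = np.nan
    cost_history: list = field(default_factory=list)
    converged: bool = False
    iterations: int = 0

    @property
    def n(self) -> int:
        return self.L.shape[0] + 1


@dataclass
class MomentTrack:
    """Exact closed-loop moments of true state and estimate.

    mu : (n, 10) mean state (estimator is unbiased, so the mean estimate is
    identical); SigmaX/SigmaHat/SigmaE : (n, 10, 10) covariances of state,
    estimate and estimation error; cross : (n, 10, 10) Cov(x-hat, e);
    s2 : (n,) expected squared sensory-noise scale E[(a + kappa d'x)^2]
    (zero where the observer has switched to the constant form);
    switched : (n,) bool switching flags.
    """
    mu: np.ndarray
    SigmaX: np.ndarray
    SigmaHat: np.ndarray
    SigmaE: np.ndarray
    cross: np.ndarray
    s2: np.ndarray
    switched: np.ndarray
    control_cost: float = 0.0   # sum_t E[u' R u] under the law that generated the track


@dataclass(frozen=True)
class SolverSettings:
    """exact_blockmin selects the controller-update flavor: False (default)
    uses the certainty-equivalent update (feedback gain independent of the
    estimate/error cross-covariance), which keeps the feedforward confined
    to the visibility-modulated subsystem; True additionally solves for the
    cross-covariance correction, making each (L_t, l_t) the exact block
    minimizer of the expected cost (the two coincide whenever the internal
    estimation noise is zero)."""
    max_iters: int = 500
    rel_tol: float = 1e-6
    damping: float = 1e-12
    init_mode: str = "classical"   # or "zero"
    exact_blockmin: bool = False

    def __post_init__(self):
        if self.max_iters < 1:
            raise InvalidParameterError("max_iters must be >= 1")
        if self.rel_tol <= 0:
            raise InvalidParameterError("rel_tol must be > 0")


def _forward(L, l, K, config: ExperimentConfig, compute_K: bool,
             damping: float = 1e-12):
    """Propagate exact joint moments of z = [x; x-hat] forward.

    If compute_K, the filter gain at each step is chosen to minimize the
    expected squared estimation error (PSD-order minimizer of the error
    covariance) and returned; otherwise the supplied K is used.
    """
    plant, noise, cost, fld = config.plant, config.noise, config.cost, config.field
    A, B, H = plant.A, plant.B, plant.H
    n = plant.n
    R = cost.R
    d = fld.d
    kappa = fld.kappa
    a = noise.a
    Oxi = np.diag(noise.omega_xi)
    Oeta = np.diag(noise.omega_eta)
    ow = noise.omega_w
    sg = noise.sigma_g
    Sf2 = noise.sigma_f_matrix ** 2
    BBt = B @ B.T

    mu = np.empty((n, NX))
    SX = np.empty((n, NX, NX))
    SH = np.empty((n, NX, NX))
    SE = np.empty((n, NX, NX))
    CR = np.empty((n, NX, NX))
    s2 = np.empty(n)
    sw = np.empty(n, dtype=bool)
    Kout = np.empty((n - 1, NX, NY)) if compute_K else np.asarray(K)

    m = config.x1()
    C = np.zeros((2 * NX, 2 * NX))
    C[:NX, :NX] = config.Sigma1()
    Jctrl = 0.0

    for t in range(n):
        Cxx = C[:NX, :NX]
        Cxh = C[:NX, NX:]
        Chh = C[NX:, NX:]
        mu[t] = m
        SX[t] = Cxx
        SH[t] = Chh
        SE[t] = Cxx - Cxh - Cxh.T + Chh
        CR[t] = Cxh.T - Chh          # Cov(x-hat, e) = Cov(x-hat, x) - Cov(x-hat)
        shat = a + kappa * (d @ m)
        sw[t] = shat <= 0.0
        s2[t] = 0.0 if sw[t] else shat ** 2 + kappa ** 2 * (d @ Cxx @ d)
        if t == n - 1:
            break

        Lt, lt = L[t], l[t]
        um = -Lt @ m - lt
        Covu = Lt @ Chh @ Lt.T
        Eu2vec = np.diag(Covu) + um ** 2
        Jctrl += np.trace(R @ Covu) + um @ R @ um

        if compute_K:
            Se = SE[t]
            N = H @ Se @ H.T + np.diag(ow + sg * s2[t])
            N[np.diag_indices_from(N)] += damping
            Kt = np.linalg.solve(N, (A @ Se @ H.T).T).T
            Kout[t] = Kt
        else:
            Kt = Kout[t]

        KH = Kt @ H
        BL = B @ Lt
        Abar = np.zeros((2 * NX, 2 * NX))
        Abar[:NX, :NX] = A
        Abar[:NX, NX:] = -BL
        Abar[NX:, :NX] = KH
        Abar[NX:, NX:] = A - KH - BL

        C = Abar @ C @ Abar.T
        # process noise (x block) and filter noise (x-hat block)
        C[:NX, :NX] += (B * (Sf2 @ Eu2vec)) @ B.T + Oxi
        C[NX:, NX:] += (Kt * (ow + sg * s2[t])) @ Kt.T + Oeta
        C = 0.5 * (C + C.T)
        m = A @ m - B @ (Lt @ m + lt)

    track = MomentTrack(mu=mu, SigmaX=SX, SigmaHat=SH, SigmaE=SE, cross=CR,
                        s2=s2, switched=sw, control_cost=Jctrl)
    return Kout, track


def kalman_pass(law: ControlLaw, config: ExperimentConfig,
                damping: float = 1e-12):
    """Recompute the filter gains for a fixed control law.

    Returns the new gain sequence together with the moment track of the
    closed loop under (law.L, law.l, new K).
    """
    return _forward(law.L, law.l, None, config, compute_K=True, damping=damping)


def control_pass(K: np.ndarray, config: ExperimentConfig, moments: MomentTrack,
                 damping: float = 1e-12, exact_blockmin: bool = False):
    """Backward sweep updating (L_t, l_t) to the exact block minimizer of the
    expected cost given the filter gains and the forward moments."""
    plant, noise, cost, fld = config.plant, config.noise, config.cost, config.field
    A, B, H = plant.A, plant.B, plant.H
    n = plant.n
    R = cost.R
    d = fld.d
    kappa = fld.kappa
    a = noise.a
    sg = noise.sigma_g
    Sf2 = noise.sigma_f_matrix ** 2
    with_delta = exact_blockmin and bool(np.any(noise.omega_eta > 0))

    Lout = np.empty((n - 1, NU, NX))
    lout = np.empty((n - 1, NU))

    S = np.zeros((2 * NX, 2 * NX))
    S[:NX, :NX] = cost.Qn
    sv = np.zeros(2 * NX)

    for t in range(n - 2, -1, -1):
        S11 = S[:NX, :NX]
        S12 = S[:NX, NX:]
        S22 = S[NX:, NX:]
        Shat = S11 + S12 + S12.T + S22
        Kt = K[t]
        KH = Kt @ H

        M = R + B.T @ Shat @ B
        M[np.diag_indices_from(M)] += np.diag(B.T @ S11 @ B) @ Sf2 + damping
        BtShatA = B.T @ Shat @ A
        L0 = np.linalg.solve(M, BtShatA)

        # Correction for the estimate-error cross-covariance.  With the
        # error-optimal filter this cross-covariance is driven purely by the
        # internal estimation noise (orthogonality principle), so it is
        # skipped exactly when omega_eta = 0; otherwise the stationarity
        # condition M L Cov(x-hat) = B~'S'A~ Cov(z, x-hat) is solved with a
        # Tikhonov-regularized inverse (flat directions of Cov(x-hat) leave
        # the gain at its certainty-equivalent value L0).
        if with_delta:
            Ceh = moments.cross[t].T        # Cov(e, x-hat)
            Chh = moments.SigmaHat[t]
            Wres = B.T @ ((S11 + S12.T) @ A + (S12 + S22) @ KH) @ Ceh
            lam = 1e-8 * (1.0 + np.trace(Chh))
            Creg = Chh + lam * np.eye(NX)
            Delta = np.linalg.solve(M, np.linalg.solve(Creg.T, Wres.T).T)
        else:
            Delta = 0.0
        Lt = L0 + Delta

        m = moments.mu[t]
        phibar = BtShatA @ m + B.T @ (sv[:NX] + sv[NX:])
        lt = np.linalg.solve(M, phibar) - Lt @ m
        Lout[t] = Lt
        lout[t] = lt

        # cost-to-go update V_t(z) = z'S z + 2 s'z + const under the new gains
        T1 = B.T @ (S11 + S12.T)            # (2,10)
        T2 = B.T @ (S12 + S22)
        Phi = np.hstack([T1 @ A + T2 @ KH, T2 @ (A - KH)])   # (2,20)
        Atil = np.zeros((2 * NX, 2 * NX))
        Atil[:NX, :NX] = A
        Atil[NX:, :NX] = KH
        Atil[NX:, NX:] = A - KH

        Snew = Atil.T @ S @ Atil
        LtM = Lt.T @ M
        Snew[NX:, NX:] += LtM @ Lt
        LtPhi = Lt.T @ Phi                   # (10,20)
        Snew[NX:, :] -= LtPhi
        Snew[:, NX:] -= LtPhi.T

        svnew = Atil.T @ sv
        Bts = B.T @ (sv[:NX] + sv[NX:])
        svnew[NX:] += Lt.T @ (M @ lt - Bts)
        svnew -= Phi.T @ lt

        if not moments.switched[t]:
            KS = Kt.T @ S22 @ Kt
            tau = float(np.sum(sg * np.diag(KS)))
            if tau != 0.0:
                Snew[:NX, :NX] += (tau * kappa ** 2) * np.outer(d, d)
                svnew[:NX] += (tau * a * kappa) * d
        S = 0.5 * (Snew + Snew.T)
        sv = svnew

    return Lout, lout


def expected_cost(law: ControlLaw, config: ExperimentConfig,
                  moments: MomentTrack | None = None) -> float:
    """Analytic expectation of the quadratic cost under the closed loop.

    Exact: the mean/covariance propagation makes no distributional
    approximation (second moments close under linear dynamics with
    signal- and state-dependent noise).
    """
    if moments is None:
        _, moments = _forward(law.L, law.l, law.K, config, compute_K=False)
    Qn = config.cost.Qn
    mN = moments.mu[-1]
    J = float(mN @ Qn @ mN + np.trace(Qn @ moments.SigmaX[-1])
              + moments.control_cost)
    return J


def classical_init(config: ExperimentConfig, damping: float = 1e-12):
    """Additive-noise LQG initialization (l = 0).

    Controller: standard finite-horizon Riccati recursion (certainty
    equivalence).  Filter: discrete Kalman recursion with the observation
    covariance frozen at its rest-state value Omega_w + sigma_g * a^2.
    """
    plant, noise, cost = config.plant, config.noise, config.cost
    A, B, H = plant.A, plant.B, plant.H
    n = plant.n
    R = cost.R

    L = np.empty((n - 1, NU, NX))
    S = cost.Qn.copy()
    for t in range(n - 2, -1, -1):
        M = R + B.T @ S @ B
        M[np.diag_indices_from(M)] += damping
        L[t] = np.linalg.solve(M, B.T @ S @ A)
        S = A.T @ S @ (A - B @ L[t])
        S = 0.5 * (S + S.T)

    K = np.empty((n - 1, NX, NY))
    W = noise.omega_w + noise.sigma_g * noise.a ** 2
    Se = config.Sigma1()
    Oxi = np.diag(noise.omega_xi)
    Oeta = np.diag(noise.omega_eta)
    for t in range(n - 1):
        N = H @ Se @ H.T + np.diag(W)
        N[np.diag_indices_from(N)] += damping
        K[t] = np.linalg.solve(N, (A @ Se @ H.T).T).T
        AK = A - K[t] @ H
        Se = AK @ Se @ AK.T + Oxi + (K[t] * W) @ K[t].T + Oeta
        Se = 0.5 * (Se + Se.T)

    return ControlLaw(L=L, l=np.zeros((n - 1, NU)), K=K)


def solve(config: ExperimentConfig, settings: SolverSettings | None = None
          ) -> ControlLaw:
    """Coordinate descent: alternate filter and controller updates until the
    expected cost converges (relative change below settings.rel_tol)."""
    if settings is None:
        settings = SolverSettings()
    config.start  # validates single-start config

    if settings.init_mode == "classical":
        law = classical_init(config, settings.damping)
    elif settings.init_mode == "zero":
        n = config.plant.n
        law = ControlLaw(L=np.zeros((n - 1, NU, NX)), l=np.zeros((n - 1, NU)),
                         K=np.zeros((n - 1, NX, NY)))
    else:
        raise InvalidParameterError(f"unknown init_mode {settings.init_mode!r}")

    J = expected_cost(law, config)
    history = [J]
    converged = False
    iters = 0
    for it in range(settings.max_iters):
        K, track = kalman_pass(law, config, settings.damping)
        L, l = control_pass(K, config, track, settings.damping,
                            settings.exact_blockmin)
        candidate = ControlLaw(L=L, l=l, K=K)
        Jnew = expected_cost(candidate, config)
        logger.debug("iteration %d: expected cost %.10g", it + 1, Jnew)
        if Jnew > J:
            # Descent safeguard with backtracking.  With internal estimation
            # noise the certainty-equivalent controller update minimizes the
            # cost of the unbiased-estimate approximation, which near its
            # fixed point can differ slightly from the exact expected cost:
            # a full step may overshoot the exact-cost minimum along the
            # update direction, so the step is shortened geometrically until
            # it descends; when no shortening descends, the alternation has
            # reached a (numerically) stationary point and stops.
            beta, best, Jbest = 1.0, None, J
            for _ in range(10):
                beta *= 0.5
                trial = ControlLaw(L=law.L + beta * (L - law.L),
                                   l=law.l + beta * (l - law.l),
                                   K=law.K + beta * (K - law.K))
                Jtrial = expected_cost(trial, config)
                if Jtrial < Jbest:
                    best, Jbest = trial, Jtrial
                    break
            if best is None:
                converged = True
                break
            candidate, Jnew = best, Jbest
        law = candidate
        history.append(Jnew)
        iters = it + 1
        if abs(J - Jnew) <= settings.rel_tol * max(abs(Jnew), 1e-300):
            converged = True
            J = Jnew
            break
        J = Jnew
    if not converged:
        warnings.warn(f"solver did not converge within {settings.max_iters} "
                      f"iterations (last rel change "
                      f"{abs(history[-2] - history[-1]) / max(abs(history[-1]), 1e-300):.2e})",
                      RuntimeWarning, stacklevel=2)
    law.expected_cost = J
    law.cost_history = history
    law.converged = converged
    law.iterations = iters
    return law


@dataclass
class DecompositionReport:
    """Controller decomposition in coordinates rotated so that the visibility
    modulation direction maps onto +x ('parallel' axis)."""
    L_rot: np.ndarray          # (n-1, 2, 10) feedback gains, rotated frame
    l_rot: np.ndarray          # (n-1, 2) feedforward, rotated frame
    l_parallel: np.ndarray     # (n-1,) feedforward along theta
    l_orthogonal: np.ndarray   # (n-1,) feedforward orthogonal to theta
    max_cross_coupling: float  # max |cross-axis element of L_rot|
    max_gain: float            # max |element of L_rot|


def decompose_controller(law: ControlLaw, field) -> DecompositionReport:
    """Report per-axis structure of the affine law after rotating the frame
    so theta maps to +x (plant dynamics are isotropic, so the rotation is a
    similarity transform of the law)."""
    th = field.theta_rad
    c, s = np.cos(th), np.sin(th)
    R2 = np.array([[c, s], [-s, c]])        # rotation by -theta
    T = np.zeros((NX, NX))
    for blk in range(5):
        T[2 * blk:2 * blk + 2, 2 * blk:2 * blk + 2] = R2
    L_rot = np.einsum("ab,tbc,dc->tad", R2, law.L, T)
    l_rot = law.l @ R2.T

    xcols = np.arange(0, NX, 2)             # parallel-axis state components
    ycols = np.arange(1, NX, 2)
    cross = max(np.abs(L_rot[:, 0][:, ycols]).max(),
                np.abs(L_rot[:, 1][:, xcols]).max())
    return DecompositionReport(
        L_rot=L_rot, l_rot=l_rot,
        l_parallel=l_rot[:, 0], l_orthogonal=l_rot[:, 1],
        max_cross_coupling=float(cross),
        max_gain=float(np.abs(L_rot).max()))
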