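"""Closed-loop stochastic rollouts of plant + estimator + control law.

A rollout advances the true state with signal-dependent motor noise, draws
an observation whose position channels carry the state-dependent noise
scale evaluated at the *realized* state (the physical cursor really is
fully visible above threshold, whereas the solver resolves the switching
against the mean trajectory), and advances the estimate with the Kalman
gains of the law.

Reproducibility: one master seed; each rollout gets an independent
substream (numpy SeedSequence spawning).  Within a rollout the noise blocks
are drawn in the fixed order: initial position offset, then F (motor), g
(state-dependent sensory), omega (additive sensory), eta (internal), xi
(dynamics).  All blocks are always drawn and scaled by their standard
deviations, so the stream layout is invariant to parameter values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import (NX, NU, NY, ExperimentConfig, alpha_of_velocity)
from .solver import ControlLaw, _forward

__all__ = ["Trajectory", "Ensemble", "rollout", "ensemble", "predict_mean"]


class SimulationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """One closed-loop trial.

    t : (n,) time grid (s); x : (n, 10) true states; xhat : (n, 10)
    estimates; u : (n-1, 2) controls; y : (n-1, 6) observations;
    alpha : (n,) visibility trace; cost : realized quadratic cost.
    """
    t: np.ndarray
    x: np.ndarray
    xhat: np.ndarray
    u: np.ndarray
    y: np.ndarray
    alpha: np.ndarray
    cost: float

    @property
    def position(self) -> np.ndarray:
        return self.x[:, :2]

    @property
    def velocity(self) -> np.ndarray:
        return self.x[:, 2:4]


@dataclass
class Ensemble:
    """Monte Carlo collection of rollouts (stacked arrays).

    x : (n_rollouts, n, 10); u : (n_rollouts, n-1, 2); alpha
    : (n_rollouts, n); cost : (n_rollouts,).
    """
    t: np.ndarray
    x: np.ndarray
    u: np.ndarray
    alpha: np.ndarray
    cost: np.ndarray
    seed: int

    @property
    def n_rollouts(self) -> int:
        return self.x.shape[0]

    @property
    def mean_traj(self) -> np.ndarray:
        return self.x.mean(axis=0)

    @property
    def sd_traj(self) -> np.ndarray:
        return self.x.std(axis=0, ddof=0)

    @property
    def mean_alpha(self) -> np.ndarray:
        return self.alpha.mean(axis=0)

    @property
    def mean_position(self) -> np.ndarray:
        return self.mean_traj[:, :2]


def _draw_noise(rng: np.random.Generator, config: ExperimentConfig):
    """Draw all noise for one rollout in the fixed block order."""
    noise = config.noise
    n = config.plant.n
    offset = rng.standard_normal(2) * config.sigma1_pos
    F = rng.standard_normal((n - 1, NU, NU)) * noise.sigma_f_matrix
    g = rng.standard_normal((n - 1, NY)) * np.sqrt(noise.sigma_g)
    w = rng.standard_normal((n - 1, NY)) * np.sqrt(noise.omega_w)
    eta = rng.standard_normal((n - 1, NX)) * np.sqrt(noise.omega_eta)
    xi = rng.standard_normal((n - 1, NX)) * np.sqrt(noise.omega_xi)
    return offset, F, g, w, eta, xi


def _propagate(law: ControlLaw, config: ExperimentConfig, offset, F, g, w,
               eta, xi, keep_obs: bool):
    """Vectorized closed loop over the leading rollout axis."""
    plant, noise, cost, fld = config.plant, config.noise, config.cost, config.field
    A, B, H = plant.A, plant.B, plant.H
    n = plant.n
    R = cost.R
    nr = offset.shape[0]
    a, kappa, d = noise.a, fld.kappa, fld.d

    x = np.empty((nr, n, NX))
    xh = np.empty((nr, n, NX))
    u = np.empty((nr, n - 1, NU))
    y = np.empty((nr, n - 1, NY)) if keep_obs else None
    x1 = config.x1()
    x[:, 0] = x1
    x[:, 0, :2] += offset
    xh[:, 0] = x1
    Jc = np.zeros(nr)

    with np.errstate(over="ignore", invalid="ignore"):   # blow-ups caught below
        for t in range(n - 1):
            xt, xht = x[:, t], xh[:, t]
            ut = -(xht @ law.L[t].T) - law.l[t]
            u[:, t] = ut
            scale = np.maximum(a + kappa * (xt @ d), 0.0)
            yt = xt @ H.T + g[:, t] * scale[:, None] + w[:, t]
            if keep_obs:
                y[:, t] = yt
            Fu = np.einsum("rij,rj->ri", F[:, t], ut)
            x[:, t + 1] = xt @ A.T + (ut + Fu) @ B.T + xi[:, t]
            xh[:, t + 1] = (xht @ A.T + ut @ B.T
                            + (yt - xht @ H.T) @ law.K[t].T + eta[:, t])
            Jc += np.einsum("ri,ij,rj->r", ut, R, ut)
            if not np.all(np.isfinite(x[:, t + 1])):
                bad = np.argwhere(~np.isfinite(x[:, t + 1]))[0]
                raise SimulationError(
                    f"non-finite state at step {t + 1} (rollout {bad[0]})")

    Qn = cost.Qn
    Jc += np.einsum("ri,ij,rj->r", x[:, -1], Qn, x[:, -1])
    alpha = np.asarray(alpha_of_velocity(x[..., 2], x[..., 3], fld))
    return x, xh, u, y, alpha, Jc


def rollout(law: ControlLaw, config: ExperimentConfig,
            rng: np.random.Generator | int | None = None) -> Trajectory:
    """Simulate a single stochastic trial."""
    if law.n != config.plant.n:
        raise ValueError("law horizon does not match config horizon")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    blocks = _draw_noise(rng, config)
    blocks = tuple(b[None] for b in blocks)
    x, xh, u, y, alpha, Jc = _propagate(law, config, *blocks, keep_obs=True)
    t = np.arange(config.plant.n) * config.plant.dt
    return Trajectory(t=t, x=x[0], xhat=xh[0], u=u[0], y=y[0],
                      alpha=alpha[0], cost=float(Jc[0]))


def ensemble(law: ControlLaw, config: ExperimentConfig, n: int | None = None,
             seed: int | None = None) -> Ensemble:
    """Monte Carlo ensemble of independent rollouts.

    Each rollout uses its own spawned substream: member i draws exactly the
    noise that ``rollout(law, config, default_rng(SeedSequence(seed).spawn(n)[i]))``
    draws (the batched state propagation may differ from the single-rollout
    path at floating-point reduction order only).  Repeated calls with the
    same (law, config, n, seed) are bitwise identical.
    """
    if n is None:
        n = config.n_rollouts
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    if seed is None:
        seed = config.seed
    children = np.random.SeedSequence(seed).spawn(n)
    drawn = [_draw_noise(np.random.default_rng(c), config) for c in children]
    blocks = tuple(np.stack([d[k] for d in drawn]) for k in range(6))
    x, xh, u, y, alpha, Jc = _propagate(law, config, *blocks, keep_obs=False)
    t = np.arange(config.plant.n) * config.plant.dt
    return Ensemble(t=t, x=x, u=u, alpha=alpha, cost=Jc, seed=seed)


def predict_mean(law: ControlLaw, config: ExperimentConfig) -> Trajectory:
    """Deterministic mean prediction (all zero-mean noises dropped).

    Mean propagation is exact for this model, so this is both the noiseless
    rollout and the expected trajectory.  The alpha trace is computed on the
    mean velocity.
    """
    _, track = _forward(law.L, law.l, law.K, config, compute_K=False)
    mu = track.mu
    n = config.plant.n
    u = np.empty((n - 1, NU))
    for t in range(n - 1):
        u[t] = -law.L[t] @ mu[t] - law.l[t]
    alpha = np.asarray(alpha_of_velocity(mu[:, 2], mu[:, 3], config.field))
    R, Qn = config.cost.R, config.cost.Qn
    cost = float(np.einsum("ti,ij,tj->", u, R, u) + mu[-1] @ Qn @ mu[-1])
    t = np.arange(n) * config.plant.dt
    return Trajectory(t=t, x=mu.copy(), xhat=mu.copy(), u=u,
                      y=mu[:-1] @ config.plant.H.T, alpha=alpha, cost=cost)
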