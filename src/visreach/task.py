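"""Task model: plant dynamics, noise model, cost, and the velocity-dependent
visibility field.

The plant is a planar point mass driven through a second-order muscle-like
low-pass filter. The 10-dimensional state is

    x = [px, py, vx, vy, fx, fy, gx, gy, tx, ty]

with cursor position p (m), velocity v (m/s), applied force f (N), muscle
intermediate state g (N) and the (static) target position t (m) folded into
the state for notational convenience. The control u is 2-dimensional and is
corrupted by signal-dependent noise, B (I + F_t) u_t, with each element of
F_t drawn i.i.d. from N(0, sigma_f^2).

The observation y = H x + g_t (a + kappa d'x) + w is 6-dimensional (position,
velocity, force). The scalar a + kappa d'x = a - kappa v_theta is the
state-dependent sensory-noise scale: d is a unit vector on the velocity
components oriented so that d'x = -v_theta, where v_theta is the velocity
component along the visibility modulation direction theta. Cursor visibility
itself is alpha = clip(kappa v_theta, 0, 1).
"""
from __future__ import annotations

from dataclasses import dataclass, field as _field, replace
import math

import numpy as np

__all__ = [
    "NX", "NU", "NY", "STATE_LABELS", "IDX",
    "PlantSpec", "NoiseSpec", "CostSpec", "VisibilityField", "ExperimentConfig",
    "build_plant", "alpha_of_velocity", "sensory_noise_scale", "make_experiment",
]

NX = 10   # state dimension
NU = 2    # control dimension
NY = 6    # observation dimension

STATE_LABELS = ("px", "py", "vx", "vy", "fx", "fy", "gx", "gy", "tx", "ty")
IDX = {name: i for i, name in enumerate(STATE_LABELS)}

# index blocks (x-axis component first, then y)
POS = slice(0, 2)
VEL = slice(2, 4)
FRC = slice(4, 6)
MUS = slice(6, 8)
TGT = slice(8, 10)


class InvalidParameterError(ValueError):
    """Raised when a physical parameter is out of its admissible range."""


@dataclass(frozen=True)
class PlantSpec:
    """Discretized linear plant.

    A, B realize, per Cartesian axis: p' = p + dt v; v' = v + dt f/m;
    f' = f + dt (g - f)/tau2; g' = g + dt (u - g)/tau1; target rows are
    identity. H observes position, velocity and force.
    """
    dt: float
    n: int
    mass: float
    tau1: float
    tau2: float
    A: np.ndarray
    B: np.ndarray
    H: np.ndarray


def build_plant(dt: float = 0.01, n: int = 102, mass: float = 1.0,
                tau1: float = 0.04, tau2: float = 0.04) -> PlantSpec:
    """Build the discrete-time plant matrices.

    Parameters
    ----------
    dt : time step (s); n : number of time steps (the horizon covers
    (n-1)*dt seconds of movement); mass : point mass (kg); tau1, tau2 :
    time constants (s) of the two-stage low-pass filter from control to
    force.  With constant control u0 and no noise the force settles to u0
    (unit steady-state gain).
    """
    if dt <= 0:
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    if n < 2:
        raise InvalidParameterError(f"n must be >= 2, got {n}")
    if mass <= 0:
        raise InvalidParameterError(f"mass must be > 0, got {mass}")
    if tau1 <= 0 or tau2 <= 0:
        raise InvalidParameterError(f"tau1/tau2 must be > 0, got {tau1}, {tau2}")

    A = np.eye(NX)
    for ax in range(2):
        A[0 + ax, 2 + ax] = dt                 # p <- v
        A[2 + ax, 4 + ax] = dt / mass          # v <- f
        A[4 + ax, 4 + ax] = 1.0 - dt / tau2    # f leak
        A[4 + ax, 6 + ax] = dt / tau2          # f <- g
        A[6 + ax, 6 + ax] = 1.0 - dt / tau1    # g leak
    B = np.zeros((NX, NU))
    B[6, 0] = dt / tau1
    B[7, 1] = dt / tau1
    H = np.zeros((NY, NX))
    H[:6, :6] = np.eye(6)
    return PlantSpec(dt=dt, n=int(n), mass=mass, tau1=tau1, tau2=tau2,
                     A=A, B=B, H=H)


@dataclass(frozen=True)
class NoiseSpec:
    """All noise sources of the model.

    sigma_f : std of each element of the signal-dependent motor-noise matrix
        F_t (unitless multiplier on u).
    omega_xi : variances of the additive dynamics noise xi_t (10,).
    omega_w : variances of the additive observation noise w_t (6,); kept
        tiny by default, which also regularizes the filter inversions.
    a : baseline state-dependent sensory noise scale.  The scale
        a - kappa*v_theta reaches zero -- the cursor becomes fully
        detectable and the observer switches to the constant noise form --
        at v_theta = a/kappa, a speed well inside the natural movement
        range (0.2 m/s at kappa = 1 s/m).
    sigma_g : variances of the elements of g_t (6,); by default only the
        position channels are nonzero, with sqrt(sigma_g)*a = 2 cm of
        position-feedback noise at rest.
    omega_eta : internal estimation noise; the default puts a 1 cm/step
        drift on the position-estimate channels, so that position
        information decays unless refreshed by vision -- this is what makes
        visibility late in the movement (rather than early) valuable.
    """
    sigma_f: float = 0.2
    omega_xi: np.ndarray = _field(default_factory=lambda: np.zeros(NX))
    omega_w: np.ndarray = _field(default_factory=lambda: np.full(NY, 1e-12))
    omega_eta: np.ndarray = _field(
        default_factory=lambda: np.r_[1e-4, 1e-4, np.zeros(8)])
    a: float = 0.2
    sigma_g: np.ndarray = _field(
        default_factory=lambda: np.r_[1e-2, 1e-2, np.zeros(4)])

    def __post_init__(self):
        for name in ("omega_xi", "omega_w", "omega_eta", "sigma_g"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if np.any(v < 0):
                raise InvalidParameterError(f"{name} must be non-negative")
        if np.any(np.asarray(self.sigma_f) < 0) or self.a < 0:
            raise InvalidParameterError("sigma_f and a must be non-negative")

    @property
    def sigma_f_matrix(self) -> np.ndarray:
        """Per-element stds of F_t as a (2, 2) matrix (sigma_f may be a
        scalar -- equal variance for every element -- or a full matrix)."""
        return np.broadcast_to(np.asarray(self.sigma_f, dtype=float),
                               (NU, NU)).copy()
        if self.omega_xi.shape != (NX,) or self.omega_eta.shape != (NX,):
            raise InvalidParameterError("omega_xi/omega_eta must have shape (10,)")
        if self.omega_w.shape != (NY,) or self.sigma_g.shape != (NY,):
            raise InvalidParameterError("omega_w/sigma_g must have shape (6,)")


@dataclass(frozen=True)
class CostSpec:
    """Quadratic cost: x_n' Qn x_n + sum_t u_t' R u_t  (running state cost Q = 0).

    Qn penalizes the final cursor-target position error (p - t), final
    velocity and final force; R is the identity, so exactly three weights
    are free.
    """
    w_pos: float = 1e6
    w_vel: float = 1e4
    w_force: float = 1e3

    @property
    def R(self) -> np.ndarray:
        return np.eye(NU)

    @property
    def Qn(self) -> np.ndarray:
        Qn = np.zeros((NX, NX))
        for ax in range(2):
            p, t = 0 + ax, 8 + ax
            Qn[p, p] += self.w_pos
            Qn[t, t] += self.w_pos
            Qn[p, t] -= self.w_pos
            Qn[t, p] -= self.w_pos
            Qn[2 + ax, 2 + ax] = self.w_vel
            Qn[4 + ax, 4 + ax] = self.w_force
        return Qn

    @property
    def Q(self) -> np.ndarray:
        return np.zeros((NX, NX))


@dataclass(frozen=True)
class VisibilityField:
    """Velocity-dependent visibility: alpha = clip(kappa * v_theta, 0, 1).

    theta : visibility modulation direction in degrees, CCW from +x.
    kappa : visibility sensitivity (s/m).
    """
    theta: float = 0.0
    kappa: float = 1.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise InvalidParameterError(f"kappa must be > 0, got {self.kappa}")

    @property
    def theta_rad(self) -> float:
        return math.radians(self.theta)

    @property
    def unit(self) -> np.ndarray:
        """Unit vector of the visibility modulation direction (2,)."""
        return np.array([math.cos(self.theta_rad), math.sin(self.theta_rad)])

    @property
    def d(self) -> np.ndarray:
        """State-dependency unit vector: d'x = -v_theta (10,)."""
        d = np.zeros(NX)
        d[VEL] = -self.unit
        return d

    def v_theta(self, vx, vy):
        return vx * math.cos(self.theta_rad) + vy * math.sin(self.theta_rad)


def alpha_of_velocity(vx, vy, field: VisibilityField):
    """Cursor visibility for a hand velocity; total and piecewise linear."""
    return np.clip(field.kappa * field.v_theta(vx, vy), 0.0, 1.0)


def sensory_noise_scale(x: np.ndarray, a: float, field: VisibilityField):
    """State-dependent sensory-noise scale a + kappa d'x, switched to 0 once
    it would become non-positive (cursor fully detectable)."""
    if a < 0:
        raise InvalidParameterError("a must be non-negative")
    x = np.asarray(x, dtype=float)
    s = a + field.kappa * (x[..., :NX] @ field.d)
    return np.maximum(s, 0.0)


@dataclass(frozen=True)
class ExperimentConfig:
    """A reaching task: one or more start positions, a single target, the
    visibility field and all model specifications."""
    starts: np.ndarray                 # (k, 2) start positions (m)
    target: np.ndarray                 # (2,) target position (m)
    field: VisibilityField = _field(default_factory=VisibilityField)
    plant: PlantSpec = _field(default_factory=build_plant)
    noise: NoiseSpec = _field(default_factory=NoiseSpec)
    cost: CostSpec = _field(default_factory=CostSpec)
    sigma1_pos: float = 0.02           # initial position-estimate error std (m)
    n_rollouts: int = 3000
    seed: int = 0

    def __post_init__(self):
        starts = np.atleast_2d(np.asarray(self.starts, dtype=float))
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "target", np.asarray(self.target, dtype=float))
        if starts.shape[1] != 2 or self.target.shape != (2,):
            raise InvalidParameterError("starts must be (k,2), target (2,)")
        if self.sigma1_pos < 0:
            raise InvalidParameterError("sigma1_pos must be non-negative")

    @property
    def n_starts(self) -> int:
        return self.starts.shape[0]

    def single(self, i: int = 0) -> "ExperimentConfig":
        """Config restricted to start i (solver and simulator operate on a
        single movement)."""
        return replace(self, starts=self.starts[i:i + 1])

    @property
    def start(self) -> np.ndarray:
        if self.n_starts != 1:
            raise InvalidParameterError(
                "config has several starts; select one with .single(i)")
        return self.starts[0]

    def x1(self) -> np.ndarray:
        """Nominal initial state (start at rest, target appended)."""
        x = np.zeros(NX)
        x[POS] = self.start
        x[TGT] = self.target
        return x

    def Sigma1(self) -> np.ndarray:
        """Initial estimation-error covariance (position only)."""
        S = np.zeros((NX, NX))
        S[0, 0] = S[1, 1] = self.sigma1_pos ** 2
        return S


EXP1_DISTANCE = 0.15    # m, center-in reaches from a 15 cm circle
EXP2_DISTANCE = 0.21    # m, single transverse right-to-left movement


def make_experiment(preset: str, kappa: float = 1.0, theta: float | None = None,
                    seed: int = 0, **overrides) -> ExperimentConfig:
    """Preset experiment geometries.

    'exp1': 12 starts equally spaced at 30 deg on a 15 cm circle, single
    central target, default kappa = 1 s/m, theta = 0 deg.
    'exp2': single 21 cm right-to-left movement, theta = 270 deg,
    kappa in {1.25, 1.0, 0.85} s/m across conditions.
    """
    if preset == "exp1":
        theta = 0.0 if theta is None else theta
        angles = np.deg2rad(np.arange(12) * 30.0)
        starts = EXP1_DISTANCE * np.c_[np.cos(angles), np.sin(angles)]
        target = np.zeros(2)
    elif preset == "exp2":
        theta = 270.0 if theta is None else theta
        starts = np.array([[EXP2_DISTANCE / 2, 0.0]])
        target = np.array([-EXP2_DISTANCE / 2, 0.0])
    else:
        raise InvalidParameterError(f"unknown experiment preset: {preset!r}")
    fld = VisibilityField(theta=theta, kappa=kappa)
    return ExperimentConfig(starts=starts, target=target, field=fld,
                            seed=seed, **overrides)
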