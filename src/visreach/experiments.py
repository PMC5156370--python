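"""End-to-end drivers: the two reaching experiments and the parameter
sensitivity scan.

Experiment 1: twelve 15 cm center-in reaches (starts at 30 degree spacing)
under a visibility field with kappa = 1 s/m; solved per direction and
simulated by Monte Carlo; kinematics (path length, signed MPE, velocity
peaks) and the across-direction alpha-variance profile are reported.

Experiment 2: one 21 cm right-to-left transverse movement with the
visibility modulation direction toward the body (270 deg), solved at the
three sensitivities kappa = 1.25, 1.0, 0.85 s/m.

Sensitivity scan: uniform sampling of a hypercube in a 24-dimensional
parameter space (8 main model parameters varied +-50%, 16 additional
parameters that default to zero or to a shared value), re-solving the
twelve Experiment-1 movements per sample (mean trajectories only) and
aggregating the alpha-variability profile.
"""
from __future__ import annotations

from dataclasses import dataclass, field as _field, replace
import logging

import numpy as np
import pandas as pd

from .task import (NY, ExperimentConfig, NoiseSpec, CostSpec,
                   build_plant, make_experiment)
from .solver import SolverSettings, solve
from .simulate import Ensemble, ensemble, predict_mean
from .analysis import alpha_variance_profile, velocity_components

__all__ = ["Exp1Result", "Exp2Result", "ScanResult", "SensitivitySpec",
           "run_experiment1", "run_experiment2", "sensitivity_scan",
           "default_reference_profile", "PARAM_NAMES"]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Experiment 1

@dataclass
class Exp1Result:
    config: ExperimentConfig            # 12-start configuration
    angles: np.ndarray                  # (12,) start angles (deg)
    laws: list                          # per-direction ControlLaw
    ensembles: list                     # per-direction Ensemble
    mean_paths: np.ndarray              # (12, n, 2)
    alpha_profiles: np.ndarray          # (12, n) mean alpha per direction
    normalized_time: np.ndarray         # (n,)
    variance_profile: np.ndarray        # (n,) across-direction alpha variance
    sd_profile: np.ndarray
    metrics: pd.DataFrame               # per-direction kinematics
    converged: np.ndarray               # (12,) solver convergence flags


def _per_rollout_kinematics(ens: Ensemble, start, target):
    seg = np.diff(ens.x[:, :, :2], axis=1)
    plen = np.hypot(seg[..., 0], seg[..., 1]).sum(axis=1)
    chord = np.asarray(target) - np.asarray(start)
    u = chord / np.hypot(*chord)
    rel = ens.x[:, :, :2] - np.asarray(start)
    dev = u[0] * rel[..., 1] - u[1] * rel[..., 0]
    idx = np.argmax(np.abs(dev), axis=1)
    mpe = dev[np.arange(len(idx)), idx]
    return plen, mpe


def run_experiment1(kappa: float = 1.0, theta: float = 0.0,
                    n_rollouts: int = 3000, seed: int = 0,
                    config: ExperimentConfig | None = None,
                    settings: SolverSettings | None = None) -> Exp1Result:
    """Solve and simulate all 12 directions of Experiment 1."""
    if config is None:
        config = make_experiment("exp1", kappa=kappa, theta=theta, seed=seed)
    angles = np.degrees(np.arctan2(config.starts[:, 1], config.starts[:, 0]))
    angles = np.round(np.mod(angles, 360.0), 9)
    dir_seeds = np.random.default_rng(seed).integers(2 ** 31, size=config.n_starts)

    laws, ensembles, rows = [], [], []
    mean_paths, alpha_profiles, converged = [], [], []
    for i in range(config.n_starts):
        cfg = config.single(i)
        law = solve(cfg, settings)
        if not law.converged:
            logger.warning("direction %d (%.0f deg): solver did not converge",
                           i, angles[i])
        ens = ensemble(law, cfg, n_rollouts, int(dir_seeds[i]))
        laws.append(law)
        ensembles.append(ens)
        converged.append(law.converged)
        mean_paths.append(ens.mean_position)
        alpha_profiles.append(ens.mean_alpha)

        pm = predict_mean(law, cfg)
        _, _, summ = velocity_components(pm, cfg.field)
        plen, mpe = _per_rollout_kinematics(ens, cfg.start, cfg.target)
        rows.append({
            "direction_deg": angles[i],
            "path_length_mean": plen.mean(), "path_length_sd": plen.std(ddof=1),
            "signed_mpe_mean": mpe.mean(), "signed_mpe_sd": mpe.std(ddof=1),
            "peak_v_theta": summ.peak_v_theta, "t_peak_theta": summ.t_peak_theta,
            "peak_v_perp": summ.peak_v_perp, "t_peak_perp": summ.t_peak_perp,
            "peak_alpha": summ.peak_alpha, "t_peak_alpha": summ.t_peak_alpha,
            "expected_cost": law.expected_cost, "converged": law.converged,
        })

    alpha_profiles = np.asarray(alpha_profiles)
    var, sd = alpha_variance_profile(alpha_profiles)
    n = config.plant.n
    return Exp1Result(
        config=config, angles=angles, laws=laws, ensembles=ensembles,
        mean_paths=np.asarray(mean_paths), alpha_profiles=alpha_profiles,
        normalized_time=np.linspace(0.0, 1.0, n),
        variance_profile=var, sd_profile=sd,
        metrics=pd.DataFrame(rows), converged=np.asarray(converged))


# ---------------------------------------------------------------------------
# Experiment 2

@dataclass
class Exp2Result:
    kappas: tuple
    configs: list
    laws: list
    ensembles: list
    mean_paths: np.ndarray              # (3, n, 2)
    v_theta_profiles: np.ndarray        # (3, n) from the mean trajectory
    alpha_profiles: np.ndarray          # (3, n) mean alpha across rollouts
    normalized_time: np.ndarray
    metrics: pd.DataFrame


def run_experiment2(kappas=(1.25, 1.0, 0.85), n_rollouts: int = 3000,
                    seed: int = 0,
                    settings: SolverSettings | None = None) -> Exp2Result:
    """Solve and simulate the single transverse movement at each visibility
    sensitivity."""
    kappas = tuple(kappas)
    if any(k <= 0 for k in kappas):
        raise ValueError("kappa values must be positive")
    k_seeds = np.random.default_rng(seed).integers(2 ** 31, size=len(kappas))
    configs, laws, ensembles, rows = [], [], [], []
    mean_paths, vth_profiles, alpha_profiles = [], [], []
    for k, kseed in zip(kappas, k_seeds):
        cfg = make_experiment("exp2", kappa=k, seed=seed)
        law = solve(cfg, settings)
        if not law.converged:
            logger.warning("kappa %.2f: solver did not converge", k)
        ens = ensemble(law, cfg, n_rollouts, int(kseed))
        pm = predict_mean(law, cfg)
        vth, _, summ = velocity_components(pm, cfg.field)
        dev = np.abs(_straight_line_deviation(ens.mean_position,
                                              cfg.start, cfg.target)).max()
        configs.append(cfg)
        laws.append(law)
        ensembles.append(ens)
        mean_paths.append(ens.mean_position)
        vth_profiles.append(vth)
        alpha_profiles.append(ens.mean_alpha)
        rows.append({
            "kappa": k, "max_deviation": dev,
            "peak_v_theta": summ.peak_v_theta, "t_peak_theta": summ.t_peak_theta,
            "peak_alpha": summ.peak_alpha, "t_peak_alpha": summ.t_peak_alpha,
            "expected_cost": law.expected_cost, "converged": law.converged,
        })
    n = configs[0].plant.n
    return Exp2Result(
        kappas=kappas, configs=configs, laws=laws, ensembles=ensembles,
        mean_paths=np.asarray(mean_paths),
        v_theta_profiles=np.asarray(vth_profiles),
        alpha_profiles=np.asarray(alpha_profiles),
        normalized_time=np.linspace(0.0, 1.0, n),
        metrics=pd.DataFrame(rows))


def _straight_line_deviation(xy, start, target):
    chord = np.asarray(target) - np.asarray(start)
    u = chord / np.hypot(*chord)
    rel = xy - np.asarray(start)
    return u[0] * rel[:, 1] - u[1] * rel[:, 0]


# ---------------------------------------------------------------------------
# Sensitivity scan

# The 24 scanned parameters: 8 main model parameters and 16 additional
# parameters that are zero (additive noise) or tied (per-element splits of
# the F_t and g_t variances) in the reference model.  Noise parameters are
# scanned on the standard-deviation scale; main parameters span +-50% of
# their defaults, zero-default parameters span fixed absolute ranges
# (0.03 m, 0.03 m/s, 0.03 N for position-, velocity- and force-related
# noise), and the F_t per-element factors span +-50% around the shared
# motor-noise std.
PARAM_NAMES = (
    "a", "sigma_g_pos_std", "w_pos", "w_vel", "w_force", "sigma_f",
    "eta_pos_std", "tau",
    "xi_pos_std", "xi_vel_std", "xi_force_std", "xi_muscle_std",
    "omega_w_pos_std", "omega_w_vel_std", "omega_w_force_std",
    "eta_vel_std", "eta_force_std", "eta_muscle_std", "eta_pos_extra_std",
    "F_factor_00", "F_factor_01", "F_factor_10", "F_factor_11",
    "sigma_g_vel_std",
)


def default_scan_ranges() -> np.ndarray:
    """(24, 2) lower/upper hypercube bounds over PARAM_NAMES."""
    noise = NoiseSpec()
    cost = CostSpec()
    plant = build_plant()
    half = lambda v: (0.5 * v, 1.5 * v)
    r = [
        half(noise.a),
        half(float(np.sqrt(noise.sigma_g[0]))),
        half(cost.w_pos), half(cost.w_vel), half(cost.w_force),
        half(float(noise.sigma_f)),
        half(float(np.sqrt(noise.omega_eta[0]))),
        half(plant.tau1),
        (0.0, 0.03), (0.0, 0.03), (0.0, 0.03), (0.0, 0.03),   # xi
        (0.0, 0.03), (0.0, 0.03), (0.0, 0.03),                # omega_w
        (0.0, 0.03), (0.0, 0.03), (0.0, 0.03), (0.0, 0.03),   # eta extras
        (0.5, 1.5), (0.5, 1.5), (0.5, 1.5), (0.5, 1.5),       # F factors
        (0.0, 0.03),                                          # g velocity
    ]
    return np.asarray(r, dtype=float)


@dataclass(frozen=True)
class SensitivitySpec:
    """Hypercube specification for the parameter-sensitivity scan.

    The reference analysis uses 1e5 samples; the default here is a
    desk-scale 1000 (the aggregate profile stabilizes far earlier).
    """
    n_samples: int = 1000
    ranges: np.ndarray = _field(default_factory=default_scan_ranges)
    seed: int = 0

    def __post_init__(self):
        r = np.asarray(self.ranges, dtype=float)
        object.__setattr__(self, "ranges", r)
        if r.shape != (24, 2):
            raise ValueError("ranges must have shape (24, 2)")
        if np.any(r[:, 0] > r[:, 1]):
            raise ValueError("ranges must be ordered lo <= hi")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def config_from_params(p, kappa: float = 1.0, theta: float = 0.0
                       ) -> ExperimentConfig:
    """Build the Experiment-1 configuration for one scan sample."""
    p = np.asarray(p, dtype=float)
    (a, sgp, wp, wv, wf, sf, etap, tau,
     xip, xiv, xif, xim, owp, owv, owf,
     etav, etaf, etam, etape, f00, f01, f10, f11, sgv) = p

    omega_xi = np.r_[xip ** 2, xip ** 2, xiv ** 2, xiv ** 2,
                     xif ** 2, xif ** 2, xim ** 2, xim ** 2, 0.0, 0.0]
    omega_w = np.full(NY, 1e-12) + np.r_[owp ** 2, owp ** 2, owv ** 2,
                                         owv ** 2, owf ** 2, owf ** 2]
    omega_eta = np.r_[etap ** 2 + etape ** 2, etap ** 2 + etape ** 2,
                      etav ** 2, etav ** 2, etaf ** 2, etaf ** 2,
                      etam ** 2, etam ** 2, 0.0, 0.0]
    sigma_f = sf * np.array([[f00, f01], [f10, f11]])
    sigma_g = np.r_[sgp ** 2, sgp ** 2, sgv ** 2, sgv ** 2, 0.0, 0.0]
    noise = NoiseSpec(sigma_f=sigma_f, omega_xi=omega_xi, omega_w=omega_w,
                      omega_eta=omega_eta, a=a, sigma_g=sigma_g)
    cost = CostSpec(w_pos=wp, w_vel=wv, w_force=wf)
    plant = build_plant(tau1=tau, tau2=tau)
    base = make_experiment("exp1", kappa=kappa, theta=theta)
    return replace(base, noise=noise, cost=cost, plant=plant)


@dataclass
class ScanResult:
    spec: SensitivitySpec
    params: np.ndarray                 # (n_samples, 24)
    profiles: np.ndarray               # (n_valid, n) alpha-sd profiles
    sample_index: np.ndarray           # (n_valid,) rows of params used
    mean_profile: np.ndarray           # (n,)
    sd_profile: np.ndarray             # (n,)
    normalized_time: np.ndarray
    best_index: int                    # sample minimizing MSE to reference
    reference: np.ndarray
    n_failed: int


SCAN_SETTINGS = SolverSettings(max_iters=60, rel_tol=1e-5)


def _alpha_sd_profile(config: ExperimentConfig,
                      settings: SolverSettings) -> np.ndarray:
    """Across-direction sd of the expected alpha profile for one parameter
    set (mean trajectories only, as in the reference analysis)."""
    profs = []
    for i in range(config.n_starts):
        cfg = config.single(i)
        law = solve(cfg, settings)
        if not law.converged:
            raise RuntimeError("solver did not converge")
        pm = predict_mean(law, cfg)
        profs.append(pm.alpha)
    _, sd = alpha_variance_profile(np.asarray(profs))
    return sd


def default_reference_profile(settings: SolverSettings = SCAN_SETTINGS
                              ) -> np.ndarray:
    """Synthetic reference variability profile generated from the model at
    its default parameters (stands in for an experimental profile, which is
    not shipped)."""
    return _alpha_sd_profile(make_experiment("exp1"), settings)


def sensitivity_scan(spec: SensitivitySpec,
                     reference_profile: np.ndarray | None = None,
                     settings: SolverSettings = SCAN_SETTINGS) -> ScanResult:
    """Uniformly sample the 24-parameter hypercube and aggregate the
    alpha-variability profiles; report the sample closest (MSE) to the
    reference profile."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ranges[:, 0], spec.ranges[:, 1]
    params = lo + (hi - lo) * rng.random((spec.n_samples, 24))
    if reference_profile is None:
        reference_profile = default_reference_profile(settings)

    profiles, kept = [], []
    n_failed = 0
    for i in range(spec.n_samples):
        try:
            profiles.append(_alpha_sd_profile(config_from_params(params[i]),
                                              settings))
            kept.append(i)
        except Exception as exc:     # per-sample failures are counted, not fatal
            n_failed += 1
            logger.warning("scan sample %d failed: %s", i, exc)
    if not profiles:
        raise RuntimeError("all scan samples failed")
    if n_failed:
        logger.warning("scan: %d/%d samples failed and were excluded",
                       n_failed, spec.n_samples)
    profiles = np.asarray(profiles)
    mse = np.mean((profiles - reference_profile) ** 2, axis=1)
    n = profiles.shape[1]
    return ScanResult(
        spec=spec, params=params, profiles=profiles,
        sample_index=np.asarray(kept, dtype=int),
        mean_profile=profiles.mean(axis=0),
        sd_profile=profiles.std(axis=0, ddof=1) if len(profiles) > 1
        else np.zeros(n),
        normalized_time=np.linspace(0.0, 1.0, n),
        best_index=int(np.asarray(kept)[np.argmin(mse)]),
        reference=np.asarray(reference_profile), n_failed=n_failed)
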