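"""Run configuration loading/saving and output serialization.

A run is fully reproducible from its YAML config snapshot plus the seed:
every model parameter is serialized, unknown keys are rejected, and the
writers emit tidy CSV (one row per rollout x timepoint), JSON gain
sequences (lossless at double precision) and a manifest with checksums.
"""
from __future__ import annotations

from dataclasses import dataclass, field as _field, asdict, replace
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import (NU, STATE_LABELS, ExperimentConfig, NoiseSpec,
                   CostSpec, build_plant, make_experiment,
                   InvalidParameterError)
from .solver import ControlLaw, SolverSettings
from .simulate import Ensemble

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config",
           "to_experiment_config", "to_solver_settings", "write_outputs",
           "law_to_json", "law_from_json", "ensemble_to_frame"]


class ConfigError(ValueError):
    """A config file failed validation; the message names the field."""


_PLANT_DEFAULTS = {"dt": 0.01, "n": 102, "mass": 1.0, "tau1": 0.04, "tau2": 0.04}
_SOLVER_DEFAULTS = {"max_iters": 500, "rel_tol": 1e-6, "damping": 1e-12,
                    "init_mode": "classical", "exact_blockmin": False}


def _noise_defaults():
    ns = NoiseSpec()
    return {
        "sigma_f": 0.2,
        "a": ns.a,
        "sigma_g": ns.sigma_g.tolist(),
        "omega_xi": ns.omega_xi.tolist(),
        "omega_w": ns.omega_w.tolist(),
        "omega_eta": ns.omega_eta.tolist(),
    }


def _cost_defaults():
    cs = CostSpec()
    return {"w_pos": cs.w_pos, "w_vel": cs.w_vel, "w_force": cs.w_force}


@dataclass
class RunConfig:
    """Flat, serializable description of a run (defaults = Experiment 1)."""
    experiment: str = "exp1"
    kappa: float = 1.0
    theta: float | None = None
    seed: int = 0
    n_rollouts: int = 3000
    sigma1_pos: float = 0.02
    plant: dict = _field(default_factory=lambda: dict(_PLANT_DEFAULTS))
    noise: dict = _field(default_factory=_noise_defaults)
    cost: dict = _field(default_factory=_cost_defaults)
    solver: dict = _field(default_factory=lambda: dict(_SOLVER_DEFAULTS))


def _merge_section(name, defaults, given):
    if given is None:
        return dict(defaults)
    if not isinstance(given, dict):
        raise ConfigError(f"section '{name}' must be a mapping")
    unknown = set(given) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    out = dict(defaults)
    out.update(given)
    return out


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    An empty file yields the full-default Experiment-1 configuration
    (kappa = 1 s/m, theta = 0 deg).  Unknown keys are rejected and value
    errors name the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    top_defaults = {"experiment": "exp1", "kappa": 1.0, "theta": None,
                    "seed": 0, "n_rollouts": 3000, "sigma1_pos": 0.02,
                    "plant": None, "noise": None, "cost": None, "solver": None}
    unknown = set(raw) - set(top_defaults)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    merged = dict(top_defaults)
    merged.update(raw)

    rc = RunConfig(
        experiment=merged["experiment"],
        kappa=merged["kappa"],
        theta=merged["theta"],
        seed=int(merged["seed"]),
        n_rollouts=int(merged["n_rollouts"]),
        sigma1_pos=float(merged["sigma1_pos"]),
        plant=_merge_section("plant", _PLANT_DEFAULTS, merged["plant"]),
        noise=_merge_section("noise", _noise_defaults(), merged["noise"]),
        cost=_merge_section("cost", _cost_defaults(), merged["cost"]),
        solver=_merge_section("solver", _SOLVER_DEFAULTS, merged["solver"]),
    )
    _validate(rc)
    return rc


def _validate(rc: RunConfig):
    if rc.experiment not in ("exp1", "exp2"):
        raise ConfigError(f"experiment: unknown preset {rc.experiment!r}")
    if rc.kappa <= 0:
        raise ConfigError(f"kappa: must be > 0, got {rc.kappa}")
    if rc.plant["n"] < 2:
        raise ConfigError(f"plant.n: must be >= 2, got {rc.plant['n']}")
    if rc.plant["dt"] <= 0:
        raise ConfigError(f"plant.dt: must be > 0, got {rc.plant['dt']}")
    if rc.n_rollouts < 1:
        raise ConfigError("n_rollouts: must be >= 1")
    if rc.sigma1_pos < 0:
        raise ConfigError("sigma1_pos: must be >= 0")
    for key in ("w_pos", "w_vel", "w_force"):
        if rc.cost[key] < 0:
            raise ConfigError(f"cost.{key}: must be >= 0")
    try:
        to_experiment_config(rc)
        to_solver_settings(rc)
    except InvalidParameterError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(rc: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(rc), sort_keys=False))


def to_experiment_config(rc: RunConfig) -> ExperimentConfig:
    noise = NoiseSpec(
        sigma_f=np.asarray(rc.noise["sigma_f"], dtype=float)
        if not np.isscalar(rc.noise["sigma_f"]) else float(rc.noise["sigma_f"]),
        omega_xi=np.asarray(rc.noise["omega_xi"], dtype=float),
        omega_w=np.asarray(rc.noise["omega_w"], dtype=float),
        omega_eta=np.asarray(rc.noise["omega_eta"], dtype=float),
        a=float(rc.noise["a"]),
        sigma_g=np.asarray(rc.noise["sigma_g"], dtype=float))
    cost = CostSpec(**{k: float(v) for k, v in rc.cost.items()})
    plant = build_plant(**rc.plant)
    base = make_experiment(rc.experiment, kappa=rc.kappa, theta=rc.theta,
                           seed=rc.seed)
    return replace(base, plant=plant, noise=noise, cost=cost,
                   sigma1_pos=rc.sigma1_pos, n_rollouts=rc.n_rollouts)


def to_solver_settings(rc: RunConfig) -> SolverSettings:
    return SolverSettings(**rc.solver)


# ---------------------------------------------------------------------------
# Output writers

def law_to_json(law: ControlLaw) -> dict:
    """Shape-annotated, double-precision-lossless gain serialization."""
    return {
        "shapes": {"L": list(law.L.shape), "l": list(law.l.shape),
                   "K": list(law.K.shape)},
        "L": law.L.tolist(), "l": law.l.tolist(), "K": law.K.tolist(),
        "expected_cost": law.expected_cost,
        "cost_history": list(law.cost_history),
        "converged": bool(law.converged),
        "iterations": int(law.iterations),
    }


def law_from_json(obj: dict) -> ControlLaw:
    law = ControlLaw(L=np.asarray(obj["L"]), l=np.asarray(obj["l"]),
                     K=np.asarray(obj["K"]),
                     expected_cost=obj["expected_cost"],
                     cost_history=list(obj["cost_history"]),
                     converged=obj["converged"],
                     iterations=obj["iterations"])
    for name in ("L", "l", "K"):
        if list(getattr(law, name).shape) != obj["shapes"][name]:
            raise ValueError(f"gain {name} shape mismatch in JSON")
    return law


def ensemble_to_frame(ens: Ensemble) -> pd.DataFrame:
    """Tidy frame: one row per rollout x timepoint (controls NaN-padded at
    the final timepoint)."""
    nr, n, _ = ens.x.shape
    u = np.full((nr, n, NU), np.nan)
    u[:, :-1] = ens.u
    frame = {
        "rollout_id": np.repeat(np.arange(nr), n),
        "t": np.tile(ens.t, nr),
    }
    for j, name in enumerate(STATE_LABELS):
        frame[name] = ens.x[:, :, j].ravel()
    frame["ux"] = u[:, :, 0].ravel()
    frame["uy"] = u[:, :, 1].ravel()
    frame["alpha"] = ens.alpha.ravel()
    return pd.DataFrame(frame)


def ensemble_summary_frame(ens: Ensemble) -> pd.DataFrame:
    mean, sd = ens.mean_traj, ens.sd_traj
    frame = {"t": ens.t}
    for j, name in enumerate(STATE_LABELS):
        frame[f"{name}_mean"] = mean[:, j]
        frame[f"{name}_sd"] = sd[:, j]
    frame["alpha_mean"] = ens.alpha.mean(axis=0)
    frame["alpha_sd"] = ens.alpha.std(axis=0)
    return pd.DataFrame(frame)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(results: dict, directory) -> dict:
    """Write run artifacts and a checksum manifest.

    results maps artifact names to objects: RunConfig ('config'),
    ControlLaw ('gains*'), Ensemble ('trajectories*'), DataFrame
    ('metrics*' / any), dict (written as JSON), ndarray (single-column CSV).
    Returns the manifest (also written as manifest.json).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for name, obj in results.items():
        if isinstance(obj, RunConfig):
            path = directory / f"{name}.yaml"
            save_config(obj, path)
        elif isinstance(obj, ControlLaw):
            path = directory / f"{name}.json"
            path.write_text(json.dumps(law_to_json(obj)))
        elif isinstance(obj, Ensemble):
            path = directory / f"{name}.csv"
            ensemble_to_frame(obj).to_csv(path, index=False)
            spath = directory / f"{name}_summary.csv"
            ensemble_summary_frame(obj).to_csv(spath, index=False)
            files.append(spath)
        elif isinstance(obj, pd.DataFrame):
            path = directory / f"{name}.csv"
            obj.to_csv(path, index=False)
        elif isinstance(obj, np.ndarray):
            path = directory / f"{name}.csv"
            pd.DataFrame({name: obj}).to_csv(path, index=False)
        elif isinstance(obj, dict):
            path = directory / f"{name}.json"
            path.write_text(json.dumps(obj, default=float))
        else:
            raise TypeError(f"cannot serialize result {name!r} "
                            f"of type {type(obj).__name__}")
        files.append(path)
    manifest = {"files": [{"name": p.name, "sha256": _sha256(p)}
                          for p in sorted(files)]}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
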