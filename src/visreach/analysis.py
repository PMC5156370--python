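"""Kinematic and visibility analyses of reaching trajectories.

Conventions: paths are resampled uniformly in time (300 points for path
summaries, 200 points for deviation correlations); normalized time is
elapsed time over movement duration, in [0, 1]; the signed maximum
perpendicular error (MPE) is positive for counter-clockwise deviation from
the straight start-to-target line.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .task import VisibilityField
from .simulate import Trajectory, Ensemble

__all__ = [
    "ResampledPath", "KinematicSummary", "UndefinedCorrelationError",
    "resample_path", "resample_ensemble", "path_length", "signed_mpe",
    "deviation_r2", "velocity_components", "alpha_variance_profile",
    "direction_anova",
]

N_RESAMPLE = 300        # points for path resampling
N_DEVIATION = 200       # points for deviation correlation


class UndefinedCorrelationError(ValueError):
    """A correlation was requested between vectors with zero variance."""


@dataclass
class ResampledPath:
    """A path resampled to N_RESAMPLE points uniform in time.

    points : (300, 2) positions; sd_ellipses : (300, 2, 2) per-point
    position covariance across an ensemble (None for a single trajectory).
    """
    points: np.ndarray
    sd_ellipses: np.ndarray | None = None


@dataclass
class KinematicSummary:
    path_length: float
    signed_mpe: float
    peak_v_theta: float
    peak_v_perp: float
    t_peak_theta: float
    t_peak_perp: float
    peak_alpha: float
    t_peak_alpha: float


def _as_path(path) -> np.ndarray:
    if isinstance(path, ResampledPath):
        return path.points
    if isinstance(path, Trajectory):
        return path.position
    return np.asarray(path, dtype=float)


def _resample_xy(t, xy, m):
    tnew = np.linspace(t[0], t[-1], m)
    return np.c_[np.interp(tnew, t, xy[:, 0]), np.interp(tnew, t, xy[:, 1])]


def resample_path(traj) -> ResampledPath:
    """Resample a trajectory's path to 300 points uniform in time
    (linear interpolation; endpoints preserved exactly)."""
    if isinstance(traj, Trajectory):
        t, xy = traj.t, traj.position
    else:
        xy = np.asarray(traj, dtype=float)
        t = np.arange(len(xy), dtype=float)
    if len(xy) < 2:
        raise ValueError("need at least two timepoints to resample a path")
    return ResampledPath(points=_resample_xy(t, xy, N_RESAMPLE))


def resample_ensemble(ens: Ensemble) -> ResampledPath:
    """Mean path with per-point position-covariance (sd) ellipses across
    an ensemble, at 300 points uniform in time."""
    t = ens.t
    pos = ens.x[:, :, :2]
    tnew = np.linspace(t[0], t[-1], N_RESAMPLE)
    # linear interpolation of every rollout onto the common grid
    idx = np.searchsorted(t, tnew, side="right").clip(1, len(t) - 1)
    w = (tnew - t[idx - 1]) / (t[idx] - t[idx - 1])
    smp = pos[:, idx - 1] * (1 - w)[None, :, None] + pos[:, idx] * w[None, :, None]
    mean = smp.mean(axis=0)
    dev = smp - mean
    cov = np.einsum("rti,rtj->tij", dev, dev) / max(smp.shape[0] - 1, 1)
    return ResampledPath(points=mean, sd_ellipses=cov)


def path_length(path) -> float:
    """Sum of consecutive Euclidean segment lengths."""
    xy = _as_path(path)
    if len(xy) < 2:
        raise ValueError("need at least two points")
    return float(np.hypot(*np.diff(xy, axis=0).T).sum())


def _signed_deviation(xy, start, target):
    """Signed perpendicular distance of each point from the start->target
    line (CCW positive)."""
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    chord = target - start
    norm = np.hypot(*chord)
    if norm == 0:
        raise ValueError("start and target coincide")
    u = chord / norm
    rel = xy - start
    return u[0] * rel[:, 1] - u[1] * rel[:, 0]


def signed_mpe(path, start, target) -> float:
    """Signed maximum perpendicular error: the signed deviation of the
    point with the largest absolute deviation from the straight line."""
    dev = _signed_deviation(_as_path(path), start, target)
    return float(dev[np.argmax(np.abs(dev))])


def deviation_r2(paths_a, paths_b, starts, targets) -> float:
    """Squared Pearson correlation between the signed straight-line
    deviations of two matched path sets, sampled at 200 points uniform in
    time along each path."""
    if len(paths_a) != len(paths_b) or len(paths_a) != len(starts):
        raise ValueError("path sets and geometry must have matching lengths")

    def devs(paths):
        out = []
        for path, s, g in zip(paths, starts, targets):
            xy = _as_path(path)
            t = np.arange(len(xy), dtype=float)
            out.append(_signed_deviation(_resample_xy(t, xy, N_DEVIATION), s, g))
        return np.concatenate(out)

    va, vb = devs(paths_a), devs(paths_b)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise UndefinedCorrelationError(
            "deviation vector has zero variance; correlation undefined")
    r = np.corrcoef(va, vb)[0, 1]
    return float(r ** 2)


def velocity_components(traj: Trajectory, field: VisibilityField):
    """Velocity components along (v_theta) and orthogonal to (v_perp) the
    visibility modulation direction, with a kinematic summary.

    Peak values are taken with their sign at the maximum magnitude for the
    orthogonal component and as the (signed) maximum for v_theta (the
    visibility-relevant extreme); peak times are in normalized time.
    """
    c, s = field.unit
    vx, vy = traj.x[:, 2], traj.x[:, 3]
    v_theta = vx * c + vy * s
    v_perp = -vx * s + vy * c
    tn = (traj.t - traj.t[0]) / (traj.t[-1] - traj.t[0])
    i_th = int(np.argmax(v_theta))
    i_pp = int(np.argmax(np.abs(v_perp)))
    i_al = int(np.argmax(traj.alpha))
    start = traj.x[0, :2]
    target = traj.x[0, 8:10]
    summary = KinematicSummary(
        path_length=path_length(traj.position),
        signed_mpe=signed_mpe(traj.position, start, target),
        peak_v_theta=float(v_theta[i_th]),
        peak_v_perp=float(v_perp[i_pp]),
        t_peak_theta=float(tn[i_th]),
        t_peak_perp=float(tn[i_pp]),
        peak_alpha=float(traj.alpha[i_al]),
        t_peak_alpha=float(tn[i_al]),
    )
    return v_theta, v_perp, summary


def alpha_variance_profile(profiles) -> tuple[np.ndarray, np.ndarray]:
    """Across-direction variance (and sd) of alpha profiles per timepoint.

    profiles : (k, m) array (or a list of equal-length 1-d arrays), one mean
    alpha profile per movement direction on a common normalized-time grid.
    Population (ddof=0) statistics across the k directions.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two direction profiles")
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"profiles are on mismatched grids: lengths {sorted(lengths)}")
    arr = np.asarray(profiles, dtype=float)
    var = arr.var(axis=0, ddof=0)
    return var, np.sqrt(var)


def direction_anova(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA over per-direction samples at one
    timepoint.  Returns (F, p); degenerate all-equal input yields F = 0,
    p = 1."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    F, p = stats.f_oneway(*groups)
    return float(F), float(p)
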