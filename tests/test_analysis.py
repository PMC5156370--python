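"""Analysis metrics: resampling, path length, signed MPE, deviation
correlation, velocity components, alpha-variance profile and the one-way
ANOVA against independent oracles."""
import numpy as np
import pytest
from scipy import stats

from visreach.analysis import (
    N_RESAMPLE, UndefinedCorrelationError,
    resample_path, path_length, signed_mpe, deviation_r2,
    velocity_components, alpha_variance_profile, direction_anova)
from visreach.simulate import Trajectory
from visreach.task import VisibilityField


def straight_path(n=50, start=(0.0, 0.0), end=(0.15, 0.0)):
    lam = np.linspace(0, 1, n)[:, None]
    return np.asarray(start) * (1 - lam) + np.asarray(end) * lam


def semicircle(n=2001, chord=0.15, ccw=True):
    """Half circle over the chord from (0,0) to (chord,0)."""
    ang = np.linspace(np.pi, 0, n) if ccw else np.linspace(-np.pi, 0, n)
    r = chord / 2
    return np.c_[r + r * np.cos(ang), np.abs(r * np.sin(ang)) * (1 if ccw else -1)]


class TestResample:
    def test_straight_path_collinear_equispaced(self):
        rp = resample_path(straight_path())
        assert rp.points.shape == (N_RESAMPLE, 2)
        seg = np.diff(rp.points, axis=0)
        assert np.allclose(seg, seg[0], atol=1e-12)

    def test_endpoints_preserved(self):
        xy = np.cumsum(np.random.default_rng(0).standard_normal((40, 2)), axis=0)
        rp = resample_path(xy)
        assert np.allclose(rp.points[0], xy[0], atol=1e-15)
        assert np.allclose(rp.points[-1], xy[-1], atol=1e-15)

    def test_idempotent_on_300_points(self):
        xy = np.c_[np.linspace(0, 1, N_RESAMPLE) ** 2,
                   np.sin(np.linspace(0, 3, N_RESAMPLE))]
        rp = resample_path(xy)
        again = resample_path(rp.points)
        assert np.abs(again.points - rp.points).max() < 1e-12

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            resample_path(np.zeros((1, 2)))


class TestPathLength:
    def test_straight(self):
        assert path_length(straight_path()) == pytest.approx(0.15)

    def test_semicircle_closed_form(self):
        r = 0.075
        assert path_length(semicircle()) == pytest.approx(np.pi * r, rel=1e-5)

    def test_translation_rotation_invariance(self):
        xy = semicircle(201)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = xy @ R.T + np.array([0.3, -0.2])
        assert path_length(moved) == pytest.approx(path_length(xy), rel=1e-12)


class TestSignedMPE:
    def test_straight_zero(self):
        assert signed_mpe(straight_path(), (0, 0), (0.15, 0)) == 0.0

    def test_ccw_semicircle(self):
        mpe = signed_mpe(semicircle(ccw=True), (0, 0), (0.15, 0))
        assert mpe == pytest.approx(+0.075, rel=1e-6)

    def test_mirror_flips_sign(self):
        xy = semicircle(ccw=True)
        mirrored = xy * np.array([1, -1])
        a = signed_mpe(xy, (0, 0), (0.15, 0))
        b = signed_mpe(mirrored, (0, 0), (0.15, 0))
        assert b == pytest.approx(-a)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(ValueError):
            signed_mpe(straight_path(), (0.1, 0.1), (0.1, 0.1))

    def test_rotation_preserves_magnitude(self):
        xy = semicircle(401)
        th = -1.2
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        a = signed_mpe(xy, (0, 0), (0.15, 0))
        b = signed_mpe(xy @ R.T, (0, 0), np.array([0.15, 0]) @ R.T)
        assert abs(b) == pytest.approx(abs(a), rel=1e-9)


class TestDeviationR2:
    def curved_set(self, amp):
        paths, starts, targets = [], [], []
        for k, a in enumerate(amp):
            lam = np.linspace(0, 1, 80)
            base = straight_path(80, (0, 0), (0.15, 0))
            base[:, 1] += a * np.sin(np.pi * lam) * (1 + 0.1 * k)
            paths.append(base)
            starts.append((0, 0))
            targets.append((0.15, 0))
        return paths, starts, targets

    def test_identical_sets_give_unity(self):
        p, s, t = self.curved_set([0.02, -0.03, 0.05])
        assert deviation_r2(p, p, s, t) == pytest.approx(1.0)

    def test_degenerate_variance_raises(self):
        p, s, t = self.curved_set([0.02, 0.03])
        flat = [straight_path(80), straight_path(80)]
        with pytest.raises(UndefinedCorrelationError):
            deviation_r2(flat, p, s, t)

    def test_matches_direct_pearson_formula(self):
        """Oracle: recompute the 200-point deviations independently and apply
        the textbook correlation formula."""
        pa, s, t = self.curved_set([0.02, -0.01, 0.04])
        pb, _, _ = self.curved_set([0.015, 0.01, 0.035])
        got = deviation_r2(pa, pb, s, t)

        def dev200(path):
            xy = np.asarray(path)
            ts = np.linspace(0, len(xy) - 1, 200)
            x = np.interp(ts, np.arange(len(xy)), xy[:, 0])
            y = np.interp(ts, np.arange(len(xy)), xy[:, 1])
            return y          # start->target line is the x axis here

        va = np.concatenate([dev200(p) for p in pa])
        vb = np.concatenate([dev200(p) for p in pb])
        n = len(va)
        num = n * (va * vb).sum() - va.sum() * vb.sum()
        den = np.sqrt(n * (va ** 2).sum() - va.sum() ** 2) * \
            np.sqrt(n * (vb ** 2).sum() - vb.sum() ** 2)
        assert got == pytest.approx((num / den) ** 2, abs=1e-12)


class TestVelocityComponents:
    def make_traj(self, vx, vy, dt=0.01, target=(0.0, 0.0)):
        n = len(vx)
        x = np.zeros((n, 10))
        x[:, 2], x[:, 3] = vx, vy
        x[:, 0] = np.cumsum(vx) * dt
        x[:, 1] = np.cumsum(vy) * dt
        x[:, 8:10] = target
        t = np.arange(n) * dt
        alpha = np.clip(vx, 0, 1)
        return Trajectory(t=t, x=x, xhat=x.copy(), u=np.zeros((n - 1, 2)),
                          y=np.zeros((n - 1, 6)), alpha=alpha, cost=0.0)

    def test_theta_zero_gives_vx(self):
        tr = self.make_traj(np.r_[0.1, 0.3, 0.2], np.r_[0.0, -0.1, 0.4])
        vth, vperp, _ = velocity_components(tr, VisibilityField(theta=0.0))
        assert np.array_equal(vth, tr.x[:, 2])
        assert np.array_equal(vperp, tr.x[:, 3])

    def test_minimum_jerk_peak_at_half_time(self):
        tau = np.linspace(0, 1, 301)
        v = 30 * tau ** 2 - 60 * tau ** 3 + 30 * tau ** 4   # min-jerk speed
        tr = self.make_traj(v * 0.15, np.zeros_like(v), target=(0.15, 0))
        _, _, summ = velocity_components(tr, VisibilityField(theta=0.0))
        assert summ.t_peak_theta == pytest.approx(0.5, abs=1 / 300)
        assert summ.path_length >= 0.15 - 1e-9


class TestAlphaVarianceProfile:
    def test_identical_profiles_zero(self):
        prof = np.tile(np.linspace(0, 1, 50), (5, 1))
        var, sd = alpha_variance_profile(prof)
        assert var.max() < 1e-30 and sd.max() < 1e-15

    def test_two_constant_profiles(self):
        prof = np.stack([np.zeros(40), np.ones(40)])
        var, _ = alpha_variance_profile(prof)
        assert np.allclose(var, 0.25)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            alpha_variance_profile([np.zeros(30), np.zeros(31)])


class TestDirectionANOVA:
    def test_matches_textbook_formula(self):
        """Oracle: F from explicit between/within sums of squares."""
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1.0, size=9) for m in (0.0, 0.4, -0.2, 0.1)]
        F, p = direction_anova(groups)
        k = len(groups)
        N = sum(len(g) for g in groups)
        grand = np.concatenate(groups).mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F_ref = (ssb / (k - 1)) / (ssw / (N - k))
        p_ref = stats.f.sf(F_ref, k - 1, N - k)
        assert F == pytest.approx(F_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_overwhelming_effect(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(10 * m, 1.0, size=12) for m in range(4)]
        _, p = direction_anova(groups)
        assert p < 1e-6

    def test_degenerate_all_equal(self):
        F, p = direction_anova([np.ones(5), np.ones(5), np.ones(5)])
        assert F == 0.0 and p == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            direction_anova([np.ones(5)])
        with pytest.raises(ValueError):
            direction_anova([np.ones(5), np.ones(1)])


def test_metrics_translation_invariant():
    xy = semicircle(301)
    shift = np.array([1.7, -2.2])
    assert path_length(xy + shift) == pytest.approx(path_length(xy))
    assert signed_mpe(xy + shift, shift, np.array([0.15, 0]) + shift) == \
        pytest.approx(signed_mpe(xy, (0, 0), (0.15, 0)))
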