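import numpy as np
import pytest

import beeflight as bf
from beeflight.drift import (
    EstimationError,
    PiecewiseLinearDriftRegressor,
    default_v_edges,
    estimate_drift_field,
    fit_angle_drift,
    fit_speed_drift,
    project_drift,
    DriftProfile,
)
from beeflight.models import PiecewiseLinearDrift
from beeflight.trajectories import KinematicSeries

from conftest import ou_series


def _profile(centers, values, se=None, dt=0.02, axis="v"):
    centers = np.asarray(centers, dtype=float)
    values = np.asarray(values, dtype=float)
    se = np.ones_like(values) if se is None else np.asarray(se, dtype=float)
    return DriftProfile(
        centers=centers, values=values, se=se,
        counts=np.full(values.size, 100.0), axis=axis, dt=dt,
    )


class TestDriftField:
    def test_noiseless_constant_series_has_zero_drift(self):
        n = 500
        k = KinematicSeries(dt=0.02, v=np.full(n, 0.3), theta=np.zeros(n), phi=np.zeros(n - 1))
        f = estimate_drift_field([k], min_count=10)
        assert np.nanmax(np.abs(f.d_phi)) == 0.0
        assert np.nanmax(np.abs(f.d_v)) == 0.0

    def test_ou_drift_matches_closed_form(self):
        # conditional mean of the exact OU transition: ((e^{-g dt}-1)/dt)(v - mu)
        mu, gamma, dt = 0.4, 2.0, 0.02
        k = ou_series(mu=mu, gamma=gamma, dt=dt, seed=2)
        f = estimate_drift_field([k], min_count=500)
        prof = project_drift(f, "v")
        ok = prof.populated
        expected = ((np.exp(-gamma * dt) - 1) / dt) * (prof.centers[ok] - mu)
        dev = np.abs(prof.values[ok] - expected) / prof.se[ok]
        assert dev.max() < 3.0

    def test_min_count_marks_missing_and_total_failure_raises(self):
        k = ou_series(n=2_000, seed=3)
        f = estimate_drift_field([k], min_count=50)
        assert np.isnan(f.d_v[f.counts < 50]).all()
        with pytest.raises(EstimationError):
            estimate_drift_field([k], min_count=10**9)

    def test_concatenation_invariance(self):
        k = ou_series(n=5_000, seed=4)
        m = 2_000
        # a 2-sample overlap in v makes the pooled increment set identical
        first = KinematicSeries(dt=k.dt, v=k.v[:m], theta=k.theta[:m], phi=k.phi[: m - 1])
        second = KinematicSeries(
            dt=k.dt, v=k.v[m - 2 :], theta=k.theta[m - 2 :], phi=k.phi[m - 2 :]
        )
        f_all = estimate_drift_field([k], min_count=20)
        f_split = estimate_drift_field([first, second], min_count=20)
        assert np.array_equal(f_all.counts, f_split.counts)
        assert np.allclose(f_all.d_v, f_split.d_v, equal_nan=True)
        assert np.allclose(f_all.d_phi, f_split.d_phi, equal_nan=True)

    def test_default_model_dv_sign_change_at_fixed_point(self, default_kinematics):
        f = estimate_drift_field([default_kinematics])
        prof = project_drift(f, "v")
        ok = prof.populated
        c, v = prof.centers[ok], prof.values[ok]
        crossing = c[np.flatnonzero(np.diff(np.sign(v)) < 0)[0]]
        assert abs(crossing - 0.27) < 0.03  # within ~a bin of the fixed point


class TestProjection:
    def test_uniform_field_projects_to_constant(self):
        k = ou_series(n=20_000, seed=5)
        f = estimate_drift_field([k], min_count=50)
        f.d_v = np.where(np.isnan(f.d_v), np.nan, 3.14)
        prof = project_drift(f, "v")
        assert np.allclose(prof.values[prof.populated], 3.14)

    def test_projection_matches_direct_1d_estimate(self):
        from scipy.stats import binned_statistic

        k = ou_series(n=50_000, seed=6)
        f = estimate_drift_field([k], min_count=1)
        prof = project_drift(f, "v")
        dv = np.diff(k.v[:-1]) / k.dt
        states = k.v[:-2]
        direct, _, _ = binned_statistic(states, dv, "mean", bins=f.v_edges)
        ok = prof.populated & ~np.isnan(direct)
        assert np.abs(prof.values[ok] - direct[ok]).max() < 1e-12


class TestAngleDrift:
    def test_exact_line_recovered(self):
        dt = 0.02
        centers = np.linspace(-3, 3, 21)
        model = fit_angle_drift(_profile(centers, -centers / dt, axis="phi", dt=dt))
        assert model.slope == pytest.approx(-1 / dt, rel=1e-12)
        assert model.decay_ratio == pytest.approx(-1.0, rel=1e-12)

    def test_zero_profile_gives_zero_slope(self):
        model = fit_angle_drift(_profile(np.linspace(-3, 3, 11), np.zeros(11), axis="phi"))
        assert model.slope == 0.0

    def test_iid_angles_decay_fully_in_one_step(self):
        # E[(phi' - phi)/dt | phi] = -phi/dt for i.i.d. turning angles
        gen = np.random.default_rng(7)
        n = 200_000
        phi = bf.wrap_angle(gen.normal(0, 0.6, n - 1))
        k = KinematicSeries(dt=0.02, v=np.full(n, 0.3), theta=np.zeros(n), phi=phi)
        f = estimate_drift_field([k], min_count=100)
        model = fit_angle_drift(project_drift(f, "phi"))
        assert abs(model.decay_ratio + 1.0) < 3 * model.decay_ratio_se

    def test_degenerate_spread_raises(self):
        with pytest.raises(EstimationError):
            fit_angle_drift(_profile([0.0, 0.0], [0.0, 0.0], axis="phi"))


class TestSpeedDrift:
    def test_exact_two_piece_recovery(self):
        truth = PiecewiseLinearDrift.from_rates(0.27, rates=(5.0, 1.0))
        centers = default_v_edges()[:-1] + 0.01
        drift = fit_speed_drift(_profile(centers, truth(centers)), n_pieces=2)
        assert drift.knots[0] == pytest.approx(0.27, abs=1e-9)
        assert np.allclose(drift.slopes, (-5.0, -1.0), atol=1e-8)
        assert drift.v_star == pytest.approx(0.27, abs=1e-9)

    def test_exact_three_piece_recovery(self):
        truth = PiecewiseLinearDrift.from_rates(0.27, rates=(5.0, 1.0, 4.0), knots=(0.55,))
        centers = default_v_edges()[:-1] + 0.01
        drift = fit_speed_drift(_profile(centers, truth(centers)), n_pieces=3)
        assert np.allclose(drift.knots, (0.27, 0.55), atol=1e-9)
        assert np.allclose(drift.slopes, (-5.0, -1.0, -4.0), atol=1e-7)

    def test_no_sign_change_raises(self):
        centers = np.linspace(0.1, 0.5, 12)
        with pytest.raises(ValueError, match="fixed point"):
            fit_speed_drift(_profile(centers, np.full(12, 0.5) + 0.1 * centers), 2)

    def test_too_few_bins_raises(self):
        with pytest.raises(EstimationError):
            fit_speed_drift(_profile([0.1, 0.2, 0.3], [0.5, 0.0, -0.5]), 2)

    def test_driftfree_random_walk_slopes_consistent_with_zero(self):
        gen = np.random.default_rng(11)
        n = 100_000
        v = 0.4 + 0.002 * gen.standard_normal(n).cumsum()
        v = np.abs(v)
        k = KinematicSeries(dt=0.02, v=v, theta=np.zeros(n), phi=np.zeros(n - 1))
        prof = project_drift(estimate_drift_field([k], min_count=200), "v")
        ok = prof.populated
        x, y, w = prof.centers[ok], prof.values[ok], 1 / prof.se[ok] ** 2
        xbar = np.average(x, weights=w)
        slope = np.sum(w * (x - xbar) * y) / np.sum(w * (x - xbar) ** 2)
        slope_se = 1 / np.sqrt(np.sum(w * (x - xbar) ** 2))
        assert abs(slope) < 3 * slope_se

    def test_default_model_slope_asymmetry(self, default_kinematics):
        # the restoring force below the preferred speed is the stronger one
        prof = project_drift(estimate_drift_field([default_kinematics]), "v")
        drift = fit_speed_drift(prof, 2)
        assert abs(drift.slopes[0]) > abs(drift.slopes[1])

    def test_two_and_three_piece_fixed_points_agree(self, default_kinematics):
        prof = project_drift(estimate_drift_field([default_kinematics]), "v")
        d2 = fit_speed_drift(prof, 2)
        d3 = fit_speed_drift(prof, 3)
        assert abs(d2.v_star - d3.v_star) < 0.02

    def test_regressor_sklearn_interface(self):
        truth = PiecewiseLinearDrift.from_rates(0.3, rates=(2.0, 1.0))
        x = np.arange(0.05, 0.71, 0.025)  # grid contains the knot at 0.3
        reg = PiecewiseLinearDriftRegressor(n_pieces=2).fit(x, truth(x))
        assert reg.get_params()["n_pieces"] == 2
        assert np.allclose(reg.predict(x), truth(x), atol=1e-8)
        assert reg.v_star_ == pytest.approx(0.3, abs=1e-8)


class TestPiecewiseLinearDrift:
    def test_from_rates_anchors_fixed_point(self):
        d = PiecewiseLinearDrift.from_rates(0.27, rates=(5.0, 1.0))
        assert d(0.27) == pytest.approx(0.0, abs=1e-15)
        assert d(0.0) == pytest.approx(5.0 * 0.27)
        assert d(0.5) == pytest.approx(-(0.5 - 0.27))

    def test_continuity_across_knots(self):
        d = PiecewiseLinearDrift.from_rates(0.27, rates=(5.0, 1.0, 4.0), knots=(0.55,))
        for k in d.knots:
            assert d(k - 1e-12) == pytest.approx(d(k + 1e-12), abs=1e-9)

    def test_no_stable_fixed_point_raises(self):
        d = PiecewiseLinearDrift(knots=(0.3,), slopes=(1.0, 2.0), value0=0.1)
        with pytest.raises(ValueError):
            _ = d.v_star
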