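import numpy as np
import pytest
from statsmodels.tsa.stattools import acf as sm_acf

import beeflight as bf
from beeflight.models import AcfModel, AngleNoiseSigma, ModelConfig, SpeedNoiseSpec
from beeflight.noise import (
    AcfEstimate,
    FitError,
    correct_discretization_variance,
    estimate_acf,
    estimate_sigma_phi,
    extract_speed_residuals,
    fit_acf_model,
    fit_sigma_model,
    quantization_residual_variance,
    quantization_speed_variance,
)
from beeflight.trajectories import KinematicSeries

from conftest import ou_series


def _series_from_v(v, dt=0.02, phi=None):
    v = np.asarray(v, dtype=float)
    phi = np.zeros(v.size - 1) if phi is None else phi
    return KinematicSeries(dt=dt, v=v, theta=np.zeros(v.size), phi=phi)


class TestSpeedResiduals:
    def test_noiseless_relaxation_gives_zero_residuals(self, default_model):
        zero = ModelConfig(
            dt=default_model.dt,
            speed_drift=default_model.speed_drift,
            angle_sigma=AngleNoiseSigma(a=0.0, b=0.1, c=0.0),
            angle_acf=AcfModel("white", {}, default_model.dt),
            speed_noise=SpeedNoiseSpec(sigma=0.0, acf=AcfModel("white", {}, default_model.dt)),
            v_init=0.6,
        )
        k = bf.simulate(zero, 300, seed=0).kinematics
        res = extract_speed_residuals(k, default_model.speed_drift)
        assert np.abs(res).max() < 1e-12

    def test_default_model_residual_sd_matches_configured(self, default_kinematics, default_model):
        res = extract_speed_residuals(default_kinematics, default_model.speed_drift)
        assert res.std() == pytest.approx(default_model.speed_noise.sigma, rel=0.05)

    def test_ou_residual_mean_near_zero(self):
        k = ou_series(n=100_000, seed=9)
        gamma, mu, dt = 2.0, 0.4, 0.02
        # exact one-step OU drift as a (degenerate) one-piece-equivalent model
        from beeflight.models import PiecewiseLinearDrift

        rate = (1 - np.exp(-gamma * dt)) / dt
        drift = PiecewiseLinearDrift.from_rates(mu, rates=(rate, rate), knots=())
        res = extract_speed_residuals(k, drift)
        assert abs(res.mean()) < 3 * res.std() / np.sqrt(res.size)


class TestSigmaPhi:
    def test_constant_sd_within_ci(self, rng):
        n = 200_000
        v = rng.uniform(0.0, 0.8, n)
        phi = bf.wrap_angle(rng.normal(0, 0.5, n - 1))
        binned = estimate_sigma_phi(
            _series_from_v(v, phi=phi), np.arange(0, 0.82, 0.02), min_count=100
        )
        ok = binned.populated
        assert ok.sum() > 30
        covered = (binned.ci_low[ok] <= 0.5) & (binned.ci_high[ok] >= 0.5)
        # the 95% CIs should cover the true SD in the vast majority of bins
        assert covered.mean() >= 0.9
        assert np.abs(binned.sigma[ok] - 0.5).max() < 0.02

    def test_default_model_sigma_decreases_and_exceeds_offset(self, default_kinematics, default_model):
        binned = estimate_sigma_phi(default_kinematics, np.arange(0, 0.82, 0.02))
        ok = binned.populated & (binned.counts > 1000)  # sampling noise in sparse bins
        s = binned.sigma[ok]
        assert np.all(s > default_model.angle_sigma.c)
        assert s[0] > s[-1]  # decays with speed

    def test_sparse_bins_marked_missing_not_zero(self, rng):
        v = rng.uniform(0.0, 0.2, 5_000)  # nothing at high speed
        phi = bf.wrap_angle(rng.normal(0, 0.5, v.size - 1))
        binned = estimate_sigma_phi(
            _series_from_v(v, phi=phi), np.arange(0, 0.82, 0.02), min_count=50
        )
        high = binned.v_centers > 0.3
        assert np.isnan(binned.sigma[high]).all()

    def test_exact_shifted_exponential_recovery(self):
        v = np.arange(0.01, 0.8, 0.02)
        truth = AngleNoiseSigma("shifted_exponential", a=0.7, b=0.15, c=0.35)
        from beeflight.noise import SigmaPhiRegressor

        reg = SigmaPhiRegressor("shifted_exponential").fit(v, truth(v), np.full(v.size, 0.01))
        assert reg.model_.a == pytest.approx(0.7, rel=1e-6)
        assert reg.model_.b == pytest.approx(0.15, rel=1e-6)
        assert reg.model_.c == pytest.approx(0.35, rel=1e-6)

    def test_constant_bins_degenerate_to_offset(self):
        from beeflight.noise import SigmaPhiRegressor

        v = np.arange(0.01, 0.8, 0.02)
        reg = SigmaPhiRegressor("shifted_exponential").fit(
            v, np.full(v.size, 0.4), np.full(v.size, 0.01)
        )
        assert reg.model_(np.array([0.1, 0.5])) == pytest.approx([0.4, 0.4], abs=1e-4)

    def test_scale_consistency(self, default_kinematics):
        edges = np.arange(0, 0.82, 0.02)
        kappa = 0.5
        b1 = estimate_sigma_phi(default_kinematics, edges)
        scaled = KinematicSeries(
            dt=default_kinematics.dt,
            v=default_kinematics.v,
            theta=default_kinematics.theta,
            phi=default_kinematics.phi * kappa,
            flagged=default_kinematics.flagged,
        )
        b2 = estimate_sigma_phi(scaled, edges)
        m1, _ = fit_sigma_model(b1)
        m2, _ = fit_sigma_model(b2)
        assert m2.a == pytest.approx(kappa * m1.a, rel=0.05)
        assert m2.c == pytest.approx(kappa * m1.c, rel=0.05)


class TestDiscretizationCorrection:
    def test_zero_delta_is_identity(self):
        assert correct_discretization_variance(1.0, 0.0, 0.02) == 1.0

    def test_boundary_floors_at_zero_with_warning(self):
        eps2 = quantization_speed_variance(0.0015, 0.02)
        assert correct_discretization_variance(2 * eps2, 0.0015, 0.02) == pytest.approx(eps2)
        with pytest.warns(RuntimeWarning):
            out = correct_discretization_variance(eps2 / 2, 0.0015, 0.02)
        assert out == 0.0

    def test_exactly_cancelling_variance(self):
        eps2 = quantization_speed_variance(0.0015, 0.02)
        with pytest.warns(RuntimeWarning):
            assert correct_discretization_variance(eps2, 0.0015, 0.02) == 0.0

    def test_monotone_in_delta(self):
        deltas = np.linspace(0, 0.003, 10)
        vals = [correct_discretization_variance(5e-3, d, 0.02) for d in deltas]
        assert np.all(np.diff(vals) <= 0)

    def test_residual_formula_reduces_to_straight_flight(self):
        assert quantization_residual_variance(0.0015, 0.02, 1.0) == pytest.approx(
            0.0015**2 / (2 * 0.02**2)
        )

    def test_quantized_residual_variance_matches_formula(self, default_model):
        # quantize a clean simulated track and compare the residual-variance
        # inflation against the derived formula
        from beeflight.synthetic import ObservationSpec, apply_observation_model

        delta = 0.0015
        sim = bf.simulate(default_model, 150_000, seed=21)
        kc = bf.derive_kinematics(sim.trajectory)
        kq = bf.derive_kinematics(
            apply_observation_model(sim.trajectory, ObservationSpec(delta=delta, gap_rate=0.0))
        )
        rc = extract_speed_residuals(kc, default_model.speed_drift)
        rq = extract_speed_residuals(kq, default_model.speed_drift)
        cbar = float(np.cos(kc.phi).mean())
        occ = np.histogram(kc.v, bins=[0, 0.27, np.inf])[0]
        slope_dt = np.average([-5.0, -1.0], weights=occ) * default_model.dt
        predicted = quantization_residual_variance(delta, default_model.dt, cbar, slope_dt)
        inflation = rq.var() - rc.var()
        assert inflation == pytest.approx(predicted, rel=0.1)


class TestAcfEstimate:
    def test_white_noise_acf_small(self, rng):
        x = rng.standard_normal(20_000)
        est = estimate_acf(x, 100)
        frac = np.mean(np.abs(est.r[1:]) < 3 / np.sqrt(x.size))
        assert est.r[0] == 1.0
        assert frac >= 0.99

    def test_ar1_matches_closed_form(self, rng):
        rho, n = 0.8, 200_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n - 1)
        for i in range(n - 1):
            x[i + 1] = rho * x[i] + eps[i]
        est = estimate_acf(x, 30)
        k = np.arange(31)
        # Bartlett bands are themselves approximate, hence the slight slack
        assert np.all(np.abs(est.r - rho**k) < 3.5 * est.large_lag_se + 1e-12)

    def test_matches_statsmodels_on_single_segment(self, rng):
        x = rng.standard_normal(5_000).cumsum()
        est = estimate_acf(x, 40)
        ref = sm_acf(x, nlags=40, adjusted=False, fft=True)
        assert np.abs(est.r - ref).max() < 1e-10

    def test_segment_pooling_matches_direct_computation(self, rng):
        # oracle: explicit per-segment sums with the pooled mean, never
        # taking a product across a segment boundary
        segs = [rng.standard_normal(n).cumsum() for n in (80, 50, 120)]
        est = estimate_acf(segs, 10)
        n_total = sum(len(s) for s in segs)
        mu = sum(s.sum() for s in segs) / n_total
        c = np.zeros(11)
        for k in range(11):
            for s in segs:
                d = s - mu
                c[k] += float(np.dot(d[: len(s) - k], d[k:]))
        c /= n_total
        assert np.abs(est.r - c / c[0]).max() < 1e-12

    def test_se_non_decreasing_and_max_lag_reduced(self, rng):
        x = rng.standard_normal(300)
        with pytest.warns(RuntimeWarning, match="reducing"):
            est = estimate_acf(x, 1_000)
        assert est.lags.size == 300
        assert np.all(np.diff(est.large_lag_se) >= -1e-15)


class TestAcfFit:
    def test_exact_difference_of_exponentials_recovery(self):
        dt = 0.02
        truth = AcfModel(
            "diff_two_exponentials", {"c1": 1.3, "tau1": 0.03, "c2": 0.3, "tau2": 0.1}, dt
        )
        lags = dt * np.arange(40)
        est = AcfEstimate(
            lags=lags, r=truth(lags), large_lag_se=np.full(40, 1e-3),
            n_effective=10**6, dt=dt,
        )
        fit, sse = fit_acf_model(est, "diff_two_exponentials")
        for name, val in truth.params.items():
            assert fit.params[name] == pytest.approx(val, rel=1e-4)
        assert sse < 1e-10

    def test_normalized_model_is_one_at_lag_zero(self):
        m = AcfModel(
            "diff_two_exponentials", {"c1": 2.6, "tau1": 0.03, "c2": 0.6, "tau2": 0.1}, 0.02
        )
        assert m.normalized()(0.0) == pytest.approx(1.0)

    def test_exclude_lags_are_ignored(self):
        dt = 0.02
        truth = AcfModel("exponential", {"c": 1.0, "tau1": 0.08}, dt)
        lags = dt * np.arange(30)
        r = truth(lags).copy()
        r[1] = -0.9  # gross artifact at lag 1
        est = AcfEstimate(lags, r, np.full(30, 1e-3), 10**6, dt)
        fit, _ = fit_acf_model(est, "exponential", exclude_lags=(1,))
        assert fit.params["tau1"] == pytest.approx(0.08, rel=1e-3)

    def test_insufficient_lags_raise(self):
        dt = 0.02
        est = AcfEstimate(dt * np.arange(3), np.array([1.0, 0.5, 0.2]),
                          np.full(3, 1e-2), 1000, dt)
        with pytest.raises(FitError):
            fit_acf_model(est, "diff_two_exponentials")
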