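"""End-to-end pipeline: clean -> estimate -> reduce -> simulate -> validate.

:func:`fit_full_model` runs the estimation chain on a trajectory dataset and
returns a complete :class:`~beeflight.models.ModelConfig` plus a diagnostics
dict; :func:`validate_model` simulates a fitted model and quantifies the
match to reference data (KS distance between speed distributions, fraction of
ACF lags outside a 2-standard-error band).  The
:class:`BumblebeeLangevinModel` estimator wraps both in a scikit-learn style
``fit`` / ``sample`` interface.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.stats import ks_2samp
from sklearn.base import BaseEstimator

from . import __version__
from .drift import (
    EstimationError,
    default_phi_edges,
    default_v_edges,
    estimate_drift_field,
    fit_angle_drift,
    fit_speed_drift,
    markov_bias_correction,
    project_drift,
    quantization_bias_correction,
)
from .models import AcfModel, ModelConfig, SpeedNoiseSpec
from .noise import (
    AcfEstimate,
    correct_discretization_variance,
    estimate_acf,
    estimate_sigma_phi,
    fit_acf_model,
    fit_sigma_model,
    extract_speed_residuals,
)
from .simulate import simulate
from .trajectories import (
    GapSpec,
    KinematicSeries,
    Trajectory,
    ZoneSet,
    derive_kinematics,
    split_and_filter,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "ValidationReport",
    "fit_full_model",
    "validate_model",
    "BumblebeeLangevinModel",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the estimation pipeline needs beyond the data itself."""

    gap_spec: GapSpec = GapSpec()
    zones: ZoneSet | None = None
    phi_bins: int = 40
    v_max: float = 0.8
    v_bin_width: float = 0.02
    min_count: int = 50
    n_drift_pieces: int = 2
    sigma_family: str = "shifted_exponential"
    speed_acf_family: str = "diff_two_exponentials"
    angle_acf_family: str = "powerlaw"
    max_lag: int = 50
    camera_delta: float = 0.0
    bias_correction_iterations: int = 2

    def to_dict(self) -> dict:
        return {
            "gap_spec": {
                "max_interpolate": self.gap_spec.max_interpolate,
                "min_split": self.gap_spec.min_split,
            },
            "zones": None
            if self.zones is None
            else {
                "centers": [list(c) for c in self.zones.centers],
                "radius": self.zones.radius,
            },
            "phi_bins": self.phi_bins,
            "v_max": self.v_max,
            "v_bin_width": self.v_bin_width,
            "min_count": self.min_count,
            "n_drift_pieces": self.n_drift_pieces,
            "sigma_family": self.sigma_family,
            "speed_acf_family": self.speed_acf_family,
            "angle_acf_family": self.angle_acf_family,
            "max_lag": self.max_lag,
            "camera_delta": self.camera_delta,
            "bias_correction_iterations": self.bias_correction_iterations,
        }

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    """Decorator-free stage wrapper: re-raise any failure with the stage name."""

    class _Ctx:
        def __init__(self, stage_name):
            self.stage_name = stage_name

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(self.stage_name, str(exc)) from exc
            return False

    return _Ctx(name)


def fit_full_model(
    dataset: list[Trajectory],
    cfg: PipelineConfig | None = None,
) -> tuple[ModelConfig, dict]:
    """Run the complete estimation chain and return (model, diagnostics).

    Stages, in order: gap/zone filtering, kinematics, 2-D drift-field
    estimation, angle-drift reduction check (slope*dt ~ -1), piecewise-linear
    speed-drift fit with finite-correlation-time bias correction, sigma_phi(v)
    estimation and fit, residual extraction, quantization correction of the
    residual variance, and parametric ACF fits for both noise terms.  The
    angle noise is classified as white when no lag beyond 0 is significant at
    2 standard errors.
    """
    cfg = PipelineConfig() if cfg is None else cfg
    diagnostics: dict = {"stages": []}

    with _stage("split_and_filter"):
        segments = split_and_filter(dataset, cfg.gap_spec, cfg.zones)
        diagnostics["n_segments"] = len(segments)
        diagnostics["stages"].append("split_and_filter")
    with _stage("derive_kinematics"):
        series = [derive_kinematics(t) for t in segments if len(t) >= 3]
        if not series:
            raise EstimationError("no segment long enough for kinematics")
        dt = series[0].dt
        diagnostics["n_steps"] = int(sum(len(s) for s in series))
        diagnostics["stages"].append("derive_kinematics")

    phi_edges = default_phi_edges(cfg.phi_bins)
    v_edges = default_v_edges(cfg.v_max, cfg.v_bin_width)
    with _stage("estimate_drift_field"):
        f2d = estimate_drift_field(series, phi_edges, v_edges, cfg.min_count)
        diagnostics["stages"].append("estimate_drift_field")

    with _stage("fit_angle_drift"):
        phi_profile = project_drift(f2d, "phi")
        angle_drift = fit_angle_drift(phi_profile)
        diagnostics["angle_drift_slope"] = angle_drift.slope
        diagnostics["angle_decay_ratio"] = angle_drift.decay_ratio
        diagnostics["angle_decay_ratio_se"] = angle_drift.decay_ratio_se
        diagnostics["stages"].append("fit_angle_drift")

    # pooled stats used by the bias corrections (computed before fitting so
    # the quantization correction can already enter the first drift fit)
    v_all = np.concatenate([s.v for s in series])
    phi_all = np.concatenate([s.phi[s.valid_phi] for s in series])
    v_mean = float(v_all.mean())
    v_var = float(v_all.var())
    mean_cos_phi = float(np.cos(phi_all).mean())

    with _stage("fit_speed_drift"):
        v_profile_raw = project_drift(f2d, "v")
        v_profile = quantization_bias_correction(
            v_profile_raw, cfg.camera_delta, mean_cos_phi, v_var, v_mean
        )
        drift = fit_speed_drift(v_profile, cfg.n_drift_pieces)
        diagnostics["stages"].append("fit_speed_drift")

    with _stage("fit_sigma_phi"):
        binned_sigma = estimate_sigma_phi(series, v_edges, cfg.min_count)
        sigma_model, sigma_sse = fit_sigma_model(binned_sigma, cfg.sigma_family)
        diagnostics["sigma_sse"] = sigma_sse
        diagnostics["stages"].append("fit_sigma_phi")

    # the quantization error in the residuals is correlated over lags 1-2
    # (shared position errors), so those lags are excluded from the ACF fit
    # on camera data, mirroring the lag-1 artifact exclusion on real data
    exclude = (1, 2) if cfg.camera_delta > 0 else ()

    def _occupancy_slope_dt(drift_model):
        bounds = np.concatenate([[0.0], np.asarray(drift_model.knots), [np.inf]])
        occ = np.histogram(v_all, bins=bounds)[0].astype(float)
        slope_dt = float(np.average(np.asarray(drift_model.slopes), weights=occ) * dt)
        return occ, slope_dt

    def _noise_from(drift_model):
        residuals = [extract_speed_residuals(s, drift_model) for s in series]
        res_all = np.concatenate(residuals)
        observed_var = float(res_all.var())
        _, slope_dt = _occupancy_slope_dt(drift_model)
        # the drift fit came from a profile with the quantization line already
        # removed, so the residuals carry the full quantization error and no
        # absorbed part needs adding back
        corrected_var = correct_discretization_variance(
            observed_var,
            cfg.camera_delta,
            dt,
            mean_cos_phi=mean_cos_phi,
            mean_drift_slope_dt=slope_dt,
        )
        if corrected_var <= 0:
            raise EstimationError("quantization correction removed all variance")
        acf_est = estimate_acf(residuals, cfg.max_lag, dt=dt)
        if cfg.camera_delta > 0 and corrected_var < observed_var:
            # quantization error is uncorrelated beyond lag 2, so rescaling
            # the raw ACF to the dynamics variance recovers the noise ACF
            # at the fitted lags
            scale = observed_var / corrected_var
            r = acf_est.r.copy()
            r[1:] *= scale
            se = acf_est.large_lag_se * scale
            acf_est = AcfEstimate(acf_est.lags, r, se, acf_est.n_effective, dt)
        acf_model, acf_sse = fit_acf_model(
            acf_est, cfg.speed_acf_family, exclude_lags=exclude
        )
        return residuals, observed_var, corrected_var, acf_est, acf_model, acf_sse

    with _stage("speed_noise"):
        residuals, obs_var, corr_var, acf_est, speed_acf, acf_sse = _noise_from(drift)
        # finite-correlation-time refinement: corrected drift -> fresh residuals
        for _ in range(cfg.bias_correction_iterations):
            corrected_profile = markov_bias_correction(
                v_profile, drift, speed_acf, corr_var, v_mean, v_var
            )
            drift = fit_speed_drift(corrected_profile, cfg.n_drift_pieces)
            residuals, obs_var, corr_var, acf_est, speed_acf, acf_sse = _noise_from(
                drift
            )
        diagnostics["residual_var_observed"] = obs_var
        diagnostics["residual_var_corrected"] = corr_var
        diagnostics["speed_acf_sse"] = acf_sse
        diagnostics["stages"].append("speed_noise")

    with _stage("angle_noise_acf"):
        angle_acf_est = estimate_acf(
            [s.phi[s.valid_phi] for s in series], cfg.max_lag, dt=dt
        )
        # colored only if some short lag clears 3 SE (a 2-SE rule fires on
        # white noise about once per 20 lags just by chance)
        short = slice(1, min(11, angle_acf_est.r.size))
        significant = (
            np.abs(angle_acf_est.r[short]) > 3.0 * angle_acf_est.large_lag_se[short]
        )
        diagnostics["angle_acf_significant_lags"] = int(significant.sum())
        if significant.any():
            angle_acf, angle_sse = fit_acf_model(angle_acf_est, cfg.angle_acf_family)
            angle_acf = angle_acf.normalized()
            diagnostics["angle_acf_sse"] = angle_sse
        else:
            angle_acf = AcfModel("white", {}, dt)
        diagnostics["stages"].append("angle_noise_acf")

    model = ModelConfig(
        dt=dt,
        speed_drift=drift,
        angle_sigma=sigma_model,
        angle_acf=angle_acf,
        speed_noise=SpeedNoiseSpec(
            sigma=float(np.sqrt(corr_var)), acf=speed_acf.normalized()
        ),
    )
    diagnostics["v_star"] = drift.v_star
    diagnostics["package_version"] = __version__
    diagnostics["config_hash"] = cfg.config_hash
    return model, diagnostics


@dataclass
class ValidationReport:
    """Quantified comparison of a simulated model against reference data.

    The thresholds usually applied to these metrics (KS < 0.05, band excess
    < 0.1) are conventions of this package, not literature values.
    """

    ks_speed: float
    acf_speed_excess: float
    acf_angle_excess: float
    n_sim: int
    n_ref: int
    seed: int
    plots_path: str | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ks_speed": self.ks_speed,
            "acf_speed_excess": self.acf_speed_excess,
            "acf_angle_excess": self.acf_angle_excess,
            "n_sim": self.n_sim,
            "n_ref": self.n_ref,
            "seed": self.seed,
            "plots_path": self.plots_path,
            **self.extra,
        }


def _band_excess(acf_a, acf_b, max_lag: int) -> float:
    k = min(max_lag, acf_a.r.size - 1, acf_b.r.size - 1)
    diff = np.abs(acf_a.r[1 : k + 1] - acf_b.r[1 : k + 1])
    band = 2.0 * np.sqrt(
        acf_a.large_lag_se[1 : k + 1] ** 2 + acf_b.large_lag_se[1 : k + 1] ** 2
    )
    return float(np.mean(diff > band))


def validate_model(
    model: ModelConfig,
    reference: list[Trajectory],
    sim_seconds: float,
    seed: int = 0,
    max_lag: int = 50,
    burn_in_frac: float = 0.1,
) -> ValidationReport:
    """Simulate ``model`` and compare speed PDF and both ACFs to reference data."""
    if not reference:
        raise ValueError("reference dataset is empty")
    if not sim_seconds >= 100 * model.dt:
        raise ValueError("sim_seconds too short for a meaningful comparison")
    ref_series = [derive_kinematics(t.require_complete()) for t in reference]
    n_steps = int(round(sim_seconds / model.dt))
    out = simulate(model, n_steps, seed=seed)
    burn = int(burn_in_frac * n_steps)
    v_sim = out.kinematics.v[burn:]
    phi_sim = out.kinematics.phi[burn:]
    v_ref = np.concatenate([s.v for s in ref_series])
    phi_ref_segments = [s.phi[s.valid_phi] for s in ref_series]
    phi_ref = np.concatenate(phi_ref_segments)

    ks = float(ks_2samp(v_sim, v_ref, method="asymp").statistic)
    lag = min(max_lag, v_sim.size // 4)
    acf_v_sim = estimate_acf(v_sim, lag, dt=model.dt)
    acf_v_ref = estimate_acf([s.v for s in ref_series], lag, dt=model.dt)
    acf_p_sim = estimate_acf(phi_sim, lag, dt=model.dt)
    acf_p_ref = estimate_acf(phi_ref_segments, lag, dt=model.dt)
    return ValidationReport(
        ks_speed=ks,
        acf_speed_excess=_band_excess(acf_v_sim, acf_v_ref, lag),
        acf_angle_excess=_band_excess(acf_p_sim, acf_p_ref, lag),
        n_sim=int(v_sim.size),
        n_ref=int(v_ref.size),
        seed=seed,
        extra={
            "n_ref_phi": int(phi_ref.size),
            "sim_clamp_count": out.clamp_count,
        },
    )


class BumblebeeLangevinModel(BaseEstimator):
    """scikit-learn style front end for the full pipeline.

    ``fit(trajectories)`` estimates every model component; ``sample(n_steps,
    seed)`` simulates the fitted model; ``validate(reference, ...)`` scores it
    against data.

    Attributes
    ----------
    model_ : ModelConfig
        The fitted flight model.
    diagnostics_ : dict
        Per-stage diagnostics (angle decay ratio, residual variances, SSEs).
    """

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config

    def fit(self, trajectories, y=None):
        cfg = self.config if self.config is not None else PipelineConfig()
        self.model_, self.diagnostics_ = fit_full_model(list(trajectories), cfg)
        return self

    def sample(self, n_steps: int, seed: int = 0):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        return simulate(self.model_, n_steps, seed=seed)

    def validate(self, reference, sim_seconds: float, seed: int = 0):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        return validate_model(self.model_, reference, sim_seconds, seed=seed)
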