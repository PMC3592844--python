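"""Stochastic-term extraction and characterization.

Subtracting the fitted deterministic drift from the observed speed changes
leaves the per-step speed noise ``xi_n = (v_{n+1} - v_n) - h_v(v_n) dt``; its
marginal SD (after removing the camera-quantization contribution) and its
autocorrelation define the speed-noise model.  The turning-angle noise is
characterized by the speed-binned SD ``sigma_phi(v)`` and the ACF of the
turning angles themselves.

ACFs use the biased normalization (divide by total N and the lag-0
autocovariance) with Bartlett's large-lag standard error; multiple gap-free
segments are pooled without ever correlating across a segment boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .models import AcfModel, AngleNoiseSigma, PiecewiseLinearDrift, _ACF_PARAMS
from .trajectories import KinematicSeries

__all__ = [
    "extract_speed_residuals",
    "BinnedSigma",
    "estimate_sigma_phi",
    "fit_sigma_model",
    "SigmaPhiRegressor",
    "quantization_speed_variance",
    "quantization_residual_variance",
    "quantization_absorbed_variance",
    "correct_discretization_variance",
    "AcfEstimate",
    "estimate_acf",
    "fit_acf_model",
    "AcfCurveRegressor",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge."""


# ---------------------------------------------------------------------------
# residuals


def extract_speed_residuals(
    series: KinematicSeries, drift: PiecewiseLinearDrift
) -> np.ndarray:
    """Per-step speed-noise residuals ``xi_n = (v_{n+1} - v_n) - h_v(v_n) dt``.

    Steps flagged as zero-displacement are excluded.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 speed samples")
    v = series.v
    ok = ~(series.flagged[:-1] | series.flagged[1:])
    xi = np.diff(v) - drift(v[:-1]) * series.dt
    return xi[ok]


# ---------------------------------------------------------------------------
# sigma_phi(v)


@dataclass
class BinnedSigma:
    """Speed-binned turning-angle SD with chi-square 95% CIs."""

    v_centers: np.ndarray
    sigma: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    se: np.ndarray
    counts: np.ndarray

    @property
    def populated(self) -> np.ndarray:
        return ~np.isnan(self.sigma)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "v_center": self.v_centers,
                "sigma": self.sigma,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "count": self.counts.astype(int),
            }
        )


def estimate_sigma_phi(series_list, v_edges, min_count: int = 50) -> BinnedSigma:
    """Sample SD of the turning angle per speed bin.

    Angles are already wrapped to (-pi, pi]; the SD is the ordinary linear SD
    of the wrapped values (the per-speed distributions are concentrated, so
    full circular statistics are not needed).  95% CIs come from the
    chi-square distribution of ``(n-1) s^2 / sigma^2``.
    """
    if isinstance(series_list, KinematicSeries):
        series_list = [series_list]
    v_edges = np.asarray(v_edges, dtype=float)
    vs, phis = [], []
    for s in series_list:
        ok = s.valid_phi
        vs.append(s.v[:-1][ok])
        phis.append(s.phi[ok])
    v = np.concatenate(vs)
    phi = np.concatenate(phis)
    nb = v_edges.size - 1
    idx = np.digitize(v, v_edges) - 1
    sigma = np.full(nb, np.nan)
    lo = np.full(nb, np.nan)
    hi = np.full(nb, np.nan)
    se = np.full(nb, np.nan)
    counts = np.zeros(nb)
    for b in range(nb):
        sel = idx == b
        n = int(sel.sum())
        counts[b] = n
        if n < max(min_count, 2):
            continue
        s = float(np.std(phi[sel], ddof=1))
        sigma[b] = s
        q_lo, q_hi = stats.chi2.ppf([0.975, 0.025], df=n - 1)
        lo[b] = s * np.sqrt((n - 1) / q_lo)
        hi[b] = s * np.sqrt((n - 1) / q_hi)
        se[b] = s / np.sqrt(2.0 * (n - 1))
    if np.all(np.isnan(sigma)):
        raise FitError("no speed bin reaches min_count for sigma_phi estimation")
    centers = 0.5 * (v_edges[:-1] + v_edges[1:])
    return BinnedSigma(centers, sigma, lo, hi, se, counts)


class SigmaPhiRegressor(BaseEstimator, RegressorMixin):
    """Weighted least-squares fit of a shifted decay law to binned angle SDs.

    Families: ``shifted_exponential`` (``a*exp(-v/b)+c``) or
    ``shifted_powerlaw`` (``a*max(v, v_floor)**(-b)+c``).

    Attributes: ``model_`` (:class:`AngleNoiseSigma`), ``sse_``.
    """

    def __init__(self, family: str = "shifted_exponential", v_floor: float = 0.01):
        self.family = family
        self.v_floor = v_floor

    def fit(self, v, sigma, se=None):
        v = np.asarray(v, dtype=float).ravel()
        y = np.asarray(sigma, dtype=float).ravel()
        if se is None:
            se_arr = np.ones_like(y)
        else:
            se_arr = np.asarray(se, dtype=float).ravel()
        ok = np.isfinite(v) & np.isfinite(y) & np.isfinite(se_arr) & (se_arr > 0)
        v, y, se_arr = v[ok], y[ok], se_arr[ok]
        if v.size < 4:
            raise FitError("need at least 4 populated bins for the sigma fit")
        c0 = max(float(y.min()), 1e-6)
        a0 = max(float(y.max() - y.min()), 1e-6)
        floor = max(self.v_floor, float(v[v > 0].min()) if np.any(v > 0) else 1e-3)
        if self.family == "shifted_exponential":
            def f(vv, a, b, c):
                return a * np.exp(-vv / b) + c
            p0 = (a0, max(np.ptp(v) / 3.0, 1e-3), c0)
            bounds = ([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf])
        elif self.family == "shifted_powerlaw":
            def f(vv, a, b, c):
                return a * np.maximum(vv, floor) ** (-b) + c
            p0 = (a0 * floor, 1.0, c0)
            bounds = ([0.0, 1e-3, 0.0], [np.inf, 10.0, np.inf])
        else:
            raise ValueError(f"unknown sigma family {self.family!r}")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    f, v, y, p0=p0, sigma=se_arr, absolute_sigma=True,
                    bounds=bounds, maxfev=20000,
                )
        except RuntimeError as exc:  # pragma: no cover - scipy message varies
            raise FitError(f"sigma_phi fit did not converge: {exc}") from exc
        resid = (y - f(v, *popt)) / se_arr
        self.sse_ = float(resid @ resid)
        a, b, c = (float(p) for p in popt)
        kwargs = {"v_floor": floor} if self.family == "shifted_powerlaw" else {}
        self.model_ = AngleNoiseSigma(self.family, a=a, b=max(b, 1e-6), c=c, **kwargs)
        return self

    def predict(self, v):
        return self.model_(np.asarray(v, dtype=float))


def fit_sigma_model(binned: BinnedSigma, family: str = "shifted_exponential"):
    """Fit sigma_phi(v) to a binned estimate; returns (AngleNoiseSigma, sse)."""
    ok = binned.populated
    reg = SigmaPhiRegressor(family=family)
    reg.fit(binned.v_centers[ok], binned.sigma[ok], binned.se[ok])
    return reg.model_, reg.sse_


# ---------------------------------------------------------------------------
# camera-quantization variance correction


def quantization_speed_variance(delta: float, dt: float) -> float:
    """Variance added to a single derived speed by position quantization.

    Each displacement endpoint carries an independent uniform rounding error of
    width ``delta`` per axis (variance ``delta^2/12``); projecting the two
    endpoint errors on the track direction gives ``2 * delta^2/12 / dt^2``.
    """
    return delta**2 / (6.0 * dt**2)


def quantization_residual_variance(
    delta: float,
    dt: float,
    mean_cos_phi: float = 1.0,
    mean_drift_slope_dt: float = 0.0,
) -> float:
    """Variance the quantization adds to the per-step speed *residuals*.

    The residual ``v_{n+1} - v_n - h(v_n) dt`` involves three positions; the
    shared middle error enters both speeds, with projections on consecutive
    track directions differing by the turning angle, and the drift term is
    evaluated at the *measured* (noisy) speed, whose error is correlated with
    the increment error:

        var = [(4 + 2 cbar) + 2 h'dt (2 + cbar)] * delta^2 / (12 dt^2),

    with ``cbar = E[cos phi]`` and ``h'dt = mean_drift_slope_dt`` the
    occupancy-weighted drift slope times dt (0 and ``cbar = 1`` reduce to
    straight flight with no drift: ``delta^2 / (2 dt^2)``).
    """
    if not -1.0 <= mean_cos_phi <= 1.0:
        raise ValueError("mean_cos_phi must lie in [-1, 1]")
    coeff = (4.0 + 2.0 * mean_cos_phi) + 2.0 * mean_drift_slope_dt * (
        2.0 + mean_cos_phi
    )
    return coeff * delta**2 / (12.0 * dt**2)


def quantization_absorbed_variance(
    delta: float,
    dt: float,
    mean_cos_phi: float,
    speed_variance: float,
    mean_drift_slope_dt: float = 0.0,
) -> float:
    """Part of the quantization residual error a fitted drift absorbs.

    The residual error is correlated with the measured speed (they share the
    middle position error): ``Cov = -[(2 + cbar) + 2 h'dt] delta^2/(12 dt^2)``.
    A drift fitted to the quantized data soaks up the corresponding linear
    component ``Cov^2 / Var(v_measured)``, so that much of the error never
    shows up in the residual variance.
    """
    cov = ((2.0 + mean_cos_phi) + 2.0 * mean_drift_slope_dt) * delta**2 / (
        12.0 * dt**2
    )
    return cov**2 / speed_variance


def correct_discretization_variance(
    observed_var: float,
    delta: float,
    dt: float,
    mean_cos_phi: float | None = None,
    speed_variance: float | None = None,
    mean_drift_slope_dt: float = 0.0,
) -> float:
    """Remove the camera-quantization contribution from a noise variance.

    With ``mean_cos_phi=None`` the single-speed error ``delta^2/(6 dt^2)`` is
    subtracted; passing the mean cosine of the turning angle switches to the
    residual-increment error (see :func:`quantization_residual_variance`),
    optionally refined by the mean drift slope.  When the residuals come from
    a drift *fitted on the quantized data itself*, additionally pass the
    measured speed variance so the part of the error already absorbed by the
    fit is not subtracted twice (see :func:`quantization_absorbed_variance`);
    this is what the pipeline does.  Negative results are floored at zero
    with a warning.
    """
    if not observed_var > 0:
        raise ValueError("observed_var must be positive")
    if mean_cos_phi is None:
        eps2 = quantization_speed_variance(delta, dt)
    else:
        eps2 = quantization_residual_variance(
            delta, dt, mean_cos_phi, mean_drift_slope_dt
        )
        if speed_variance is not None:
            eps2 -= quantization_absorbed_variance(
                delta, dt, mean_cos_phi, speed_variance, mean_drift_slope_dt
            )
    corrected = observed_var - eps2
    if corrected <= 0:
        warnings.warn(
            "quantization error variance exceeds the observed variance; "
            "corrected variance floored at 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return max(corrected, 0.0)
    return corrected


# ---------------------------------------------------------------------------
# autocorrelation estimation


@dataclass
class AcfEstimate:
    """Sample ACF with Bartlett large-lag standard errors.

    ``lags`` are in seconds (lag 0 included, ``r[0] = 1``); ``large_lag_se`` is
    ``sqrt((1 + 2 sum_{j<k} r_j^2) / N)`` and is non-decreasing in the lag.
    """

    lags: np.ndarray
    r: np.ndarray
    large_lag_se: np.ndarray
    n_effective: int
    dt: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_s": self.lags, "r": self.r, "large_lag_se": self.large_lag_se}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _acovf_fft(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Unnormalized autocovariance sums sum_t x_t x_{t+k} for k = 0..max_lag."""
    n = x.size
    nfft = 1
    while nfft < 2 * n:
        nfft <<= 1
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return acov


def estimate_acf(series, max_lag: int, dt: float = 1.0) -> AcfEstimate:
    """Biased-normalization sample ACF, pooled over gap-free segments.

    ``series`` is a 1-D array or a list of 1-D arrays (segments).  Per-lag
    cross products never span a segment boundary; segments contribute with
    their natural (length) weight, and the global mean over all samples is
    removed.  If ``max_lag`` is not resolvable by the longest segment it is
    reduced with a warning.
    """
    if isinstance(series, np.ndarray) and series.ndim == 1:
        segments = [series]
    else:
        segments = [np.asarray(s, dtype=float).ravel() for s in series]
    segments = [s for s in segments if s.size >= 2]
    if not segments:
        raise ValueError("estimate_acf needs at least one segment of length >= 2")
    n_total = sum(s.size for s in segments)
    longest = max(s.size for s in segments)
    if max_lag >= longest:
        warnings.warn(
            f"max_lag={max_lag} >= longest segment ({longest}); reducing",
            RuntimeWarning,
            stacklevel=2,
        )
        max_lag = longest - 1
    mean = sum(float(s.sum()) for s in segments) / n_total
    sums = np.zeros(max_lag + 1)
    for s in segments:
        x = s - mean
        k = min(max_lag, x.size - 1)
        sums[: k + 1] += _acovf_fft(x, k)
    c = sums / n_total  # biased normalization: always divide by total N
    if c[0] <= 0:
        # constant input: degenerate white ACF rather than a hard failure
        warnings.warn(
            "zero-variance series; returning the degenerate white ACF",
            RuntimeWarning,
            stacklevel=2,
        )
        r = np.zeros(max_lag + 1)
        r[0] = 1.0
        se = np.full(max_lag + 1, 1.0 / np.sqrt(n_total))
        return AcfEstimate(
            lags=dt * np.arange(max_lag + 1), r=r, large_lag_se=se,
            n_effective=n_total, dt=dt,
        )
    r = c / c[0]
    # Bartlett: var(r_k) = (1 + 2 sum_{j=1}^{k-1} r_j^2) / N  (statsmodels convention)
    contrib = np.zeros(max_lag + 1)
    if max_lag >= 2:
        contrib[2:] = r[1:max_lag] ** 2
    se = np.sqrt((1.0 + 2.0 * np.cumsum(contrib)) / n_total)
    lags = dt * np.arange(max_lag + 1)
    return AcfEstimate(lags=lags, r=r, large_lag_se=se, n_effective=n_total, dt=dt)


# ---------------------------------------------------------------------------
# parametric ACF fits


_P0 = {
    "exponential": lambda dt: ([1.0, 5 * dt], ([0, dt / 20], [10, 1e4 * dt])),
    "powerlaw": lambda dt: ([1.0, 2.0], ([0, 0.05], [10, 30.0])),
    "diff_two_exponentials": lambda dt: (
        [1.2, 0.7 * dt, 0.2, 4 * dt],
        ([0, dt / 50, 0, dt / 50], [20, 1e4 * dt, 20, 1e4 * dt]),
    ),
    "diff_two_powerlaws": lambda dt: (
        [1.2, 3.0, 0.2, 0.5],
        ([0, 0.05, 0, 0.05], [20, 30, 20, 30]),
    ),
    "diff_exp_powerlaw": lambda dt: (
        [1.2, 0.7 * dt, 0.2, 0.5],
        ([0, dt / 50, 0, 0.05], [20, 1e4 * dt, 20, 30]),
    ),
}


class AcfCurveRegressor(BaseEstimator, RegressorMixin):
    """Weighted least-squares fit of a parametric ACF family to a sample ACF.

    Weights are ``1/se^2``; lags listed in ``exclude_lags`` (step units) are
    omitted — by convention lag 1 for speed-noise fits on camera data, where a
    quantization artifact distorts the first lag.

    Attributes: ``model_`` (:class:`AcfModel`), ``sse_``.
    """

    def __init__(
        self,
        family: str = "diff_two_exponentials",
        exclude_lags: tuple = (),
        lag_range: tuple | None = None,
    ):
        self.family = family
        self.exclude_lags = exclude_lags
        self.lag_range = lag_range

    def fit(self, acf: AcfEstimate):
        if self.family not in _ACF_PARAMS or self.family == "white":
            raise ValueError(f"cannot fit ACF family {self.family!r}")
        dt = acf.dt
        k = np.rint(acf.lags / dt).astype(int)
        keep = np.ones(k.size, dtype=bool)
        if self.lag_range is not None:
            keep &= (k >= self.lag_range[0]) & (k <= self.lag_range[1])
        keep &= ~np.isin(k, np.asarray(list(self.exclude_lags), dtype=int))
        tau = acf.lags[keep]
        y = acf.r[keep]
        se = np.where(acf.large_lag_se[keep] > 0, acf.large_lag_se[keep], 1.0 / np.sqrt(acf.n_effective))
        names = _ACF_PARAMS[self.family]
        if tau.size <= len(names):
            raise FitError("not enough lags to fit this ACF family")

        def f(t, *p):
            return AcfModel(self.family, dict(zip(names, p)), dt)(t)

        p0, bounds = _P0[self.family](dt)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    f, tau, y, p0=p0, sigma=se, absolute_sigma=True,
                    bounds=bounds, maxfev=40000,
                )
        except RuntimeError as exc:  # pragma: no cover
            raise FitError(f"ACF fit ({self.family}) did not converge: {exc}") from exc
        resid = (y - f(tau, *popt)) / se
        self.sse_ = float(resid @ resid)
        self.model_ = AcfModel(self.family, dict(zip(names, map(float, popt))), dt)
        return self

    def predict(self, tau):
        return self.model_(np.asarray(tau, dtype=float))


def fit_acf_model(
    acf: AcfEstimate,
    family: str = "diff_two_exponentials",
    lag_range: tuple | None = None,
    exclude_lags: tuple = (),
):
    """Fit a parametric ACF model; returns (AcfModel, weighted SSE)."""
    reg = AcfCurveRegressor(family=family, exclude_lags=exclude_lags, lag_range=lag_range)
    reg.fit(acf)
    return reg.model_, reg.sse_
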