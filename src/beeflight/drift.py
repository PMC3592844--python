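"""Conditional-moment (Kramers-Moyal) drift estimation and parametric fits.

The deterministic parts of the coupled speed/turning-angle Langevin
description are estimated as binned conditional averages of one-step
increments,

    d(phi, v) = < (Delta phi / dt, Delta v / dt) | (phi_n, v_n) in bin >,

then projected onto each axis and fitted: the turning-angle drift by a line
through the origin (whose slope times dt should be ~ -1 when the angle relaxes
fully within one observation step), the speed drift by a continuous piecewise
linear function with 1 or 2 grid-searched changepoints, whose downward zero
crossing is the preferred flight speed ``v_star``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binned_statistic_2d
from sklearn.base import BaseEstimator, RegressorMixin

from .models import AcfModel, PiecewiseLinearDrift
from .trajectories import KinematicSeries

__all__ = [
    "DriftField2D",
    "DriftProfile",
    "AngleDriftModel",
    "EstimationError",
    "default_phi_edges",
    "default_v_edges",
    "estimate_drift_field",
    "project_drift",
    "fit_angle_drift",
    "fit_speed_drift",
    "PiecewiseLinearDriftRegressor",
    "markov_bias_correction",
    "quantization_bias_correction",
]


class EstimationError(RuntimeError):
    """Raised when an estimation stage cannot produce a usable result."""


def default_phi_edges(n_bins: int = 40) -> np.ndarray:
    return np.linspace(-np.pi, np.pi, n_bins + 1)


def default_v_edges(v_max: float = 0.8, width: float = 0.02) -> np.ndarray:
    return np.arange(0.0, v_max + width / 2, width)


@dataclass
class DriftField2D:
    """Binned drift vector field over (phi, v) state space.

    Bins with fewer than ``min_count`` samples carry NaN, not a number.
    ``se_*`` are standard errors of the bin means (sample SD / sqrt(count)).
    """

    phi_edges: np.ndarray
    v_edges: np.ndarray
    d_phi: np.ndarray
    d_v: np.ndarray
    counts: np.ndarray
    se_phi: np.ndarray
    se_v: np.ndarray
    min_count: int
    dt: float = np.nan
    # per-bin mean conditioning states; regressing against these instead of
    # the geometric bin centers avoids the within-bin attenuation bias that a
    # concentrated state distribution would otherwise introduce
    mean_phi: np.ndarray = None  # type: ignore[assignment]
    mean_v: np.ndarray = None  # type: ignore[assignment]

    @property
    def phi_centers(self) -> np.ndarray:
        return 0.5 * (self.phi_edges[:-1] + self.phi_edges[1:])

    @property
    def v_centers(self) -> np.ndarray:
        return 0.5 * (self.v_edges[:-1] + self.v_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (phi, v) bin."""
        pc, vc = np.meshgrid(self.phi_centers, self.v_centers, indexing="ij")
        return pd.DataFrame(
            {
                "phi_center": pc.ravel(),
                "v_center": vc.ravel(),
                "count": self.counts.ravel().astype(int),
                "d_phi": self.d_phi.ravel(),
                "se_phi": self.se_phi.ravel(),
                "d_v": self.d_v.ravel(),
                "se_v": self.se_v.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class DriftProfile:
    """1-D projection of the drift field: bin centers, values and SEs."""

    centers: np.ndarray
    values: np.ndarray
    se: np.ndarray
    counts: np.ndarray
    axis: str
    dt: float

    @property
    def populated(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass(frozen=True)
class AngleDriftModel:
    """Linear turning-angle drift ``d_phi = slope * phi`` (slope <= 0, 1/s).

    ``decay_ratio = slope * dt`` is the one-step-decay diagnostic: -1 means the
    angle relaxes to zero within a single observation step.
    """

    slope: float
    slope_se: float
    dt: float

    @property
    def decay_ratio(self) -> float:
        return self.slope * self.dt

    @property
    def decay_ratio_se(self) -> float:
        return self.slope_se * self.dt


def _increments(series_list):
    """Pool state/increment tuples across series, excluding flagged steps."""
    phis, vs, dphis, dvs = [], [], [], []
    dt = None
    for s in series_list:
        if dt is None:
            dt = s.dt
        elif not np.isclose(dt, s.dt, rtol=1e-9):
            raise ValueError("all series must share dt")
        if len(s.phi) < 2:
            continue
        # state (phi_n, v_n); increments to phi_{n+1} and v_{n+1}
        ok = s.valid_phi[:-1] & s.valid_phi[1:]
        phis.append(s.phi[:-1][ok])
        vs.append(s.v[:-2][ok])
        # plain difference of the wrapped angles: the turning angle is a
        # bounded variable, and wrapping the increment itself would bias the
        # conditional mean toward zero whenever |phi' - phi| can exceed pi
        dphis.append(np.diff(s.phi)[ok] / dt)
        dvs.append(np.diff(s.v[:-1])[ok] / dt)
    if not phis:
        raise EstimationError("no usable increments in input series")
    return (
        dt,
        np.concatenate(phis),
        np.concatenate(vs),
        np.concatenate(dphis),
        np.concatenate(dvs),
    )


def estimate_drift_field(
    series_list,
    phi_edges=None,
    v_edges=None,
    min_count: int = 50,
) -> DriftField2D:
    """Estimate the drift vector field by binned conditional means.

    For each (phi, v) bin the drift components are the means of the one-step
    increments ``((phi_{n+1}-phi_n)/dt, (v_{n+1}-v_n)/dt)`` over all steps
    whose state falls in the bin; SEs are sample SD / sqrt(count).
    """
    if isinstance(series_list, KinematicSeries):
        series_list = [series_list]
    phi_edges = default_phi_edges() if phi_edges is None else np.asarray(phi_edges)
    v_edges = default_v_edges() if v_edges is None else np.asarray(v_edges)
    if np.any(np.diff(phi_edges) <= 0) or np.any(np.diff(v_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    dt, phi, v, dphi, dv = _increments(series_list)

    bins = [phi_edges, v_edges]
    counts, _, _, _ = binned_statistic_2d(phi, v, None, "count", bins=bins)
    mean_states = {}
    for name, state in (("phi", phi), ("v", v)):
        ms, _, _, _ = binned_statistic_2d(phi, v, state, "mean", bins=bins)
        ms[counts < min_count] = np.nan
        mean_states[name] = ms
    out = {}
    for name, target in (("phi", dphi), ("v", dv)):
        mean, _, _, _ = binned_statistic_2d(phi, v, target, "mean", bins=bins)
        sq, _, _, _ = binned_statistic_2d(phi, v, target**2, "mean", bins=bins)
        with np.errstate(invalid="ignore"):
            var = np.maximum(sq - mean**2, 0.0)
            sd = np.sqrt(var * counts / np.maximum(counts - 1, 1))
            se = sd / np.sqrt(np.maximum(counts, 1))
        low = counts < min_count
        mean[low] = np.nan
        se[low] = np.nan
        out[name] = (mean, se)
    if np.all(counts < min_count):
        raise EstimationError(
            f"no (phi, v) bin reaches min_count={min_count}; too little data"
        )
    return DriftField2D(
        phi_edges=phi_edges,
        v_edges=v_edges,
        d_phi=out["phi"][0],
        se_phi=out["phi"][1],
        d_v=out["v"][0],
        se_v=out["v"][1],
        counts=counts,
        min_count=min_count,
        dt=dt,
        mean_phi=mean_states["phi"],
        mean_v=mean_states["v"],
    )


def project_drift(field: DriftField2D, axis: str, dt: float | None = None) -> DriftProfile:
    """Project the 2-D drift field onto one axis by count-weighted averaging.

    ``axis='phi'`` keeps the turning-angle axis and averages ``d_phi`` over
    speed bins; ``axis='v'`` keeps the speed axis and averages ``d_v`` over
    angle bins.  Missing bins are excluded from the weights.
    """
    if axis == "phi":
        values2d, se2d = field.d_phi, field.se_phi
        centers = field.phi_centers
        mean_state = field.mean_phi
        red_axis = 1
    elif axis == "v":
        values2d, se2d = field.d_v, field.se_v
        centers = field.v_centers
        mean_state = field.mean_v
        red_axis = 0
    else:
        raise ValueError("axis must be 'phi' or 'v'")
    ok = ~np.isnan(values2d)
    w = np.where(ok, field.counts, 0.0)
    wsum = w.sum(axis=red_axis)
    if np.all(wsum == 0):
        raise EstimationError(f"no populated bins to project onto axis {axis!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.nansum(w * values2d, axis=red_axis) / wsum
        se = np.sqrt(np.nansum((w * se2d) ** 2, axis=red_axis)) / wsum
        if mean_state is not None:
            # per-row mean conditioning state: the unbiased regression abscissa
            mc = np.nansum(w * mean_state, axis=red_axis) / wsum
            centers = np.where(wsum > 0, mc, centers)
    vals[wsum == 0] = np.nan
    se[wsum == 0] = np.nan
    return DriftProfile(
        centers=centers, values=vals, se=se, counts=wsum, axis=axis,
        dt=dt if dt is not None else field.dt,
    )


def fit_angle_drift(profile: DriftProfile, dt: float | None = None) -> AngleDriftModel:
    """Weighted least-squares line through the origin on the angle-drift profile.

    Weights are 1/SE^2; missing bins are dropped.  Returns the slope (1/s) and
    its SE; the ``decay_ratio`` diagnostic ``slope*dt`` is ~ -1 when the
    turning angle decays fully within one observation step.
    """
    dt = profile.dt if dt is None else dt
    if not np.isfinite(dt):
        raise ValueError("fit_angle_drift needs the sampling interval dt")
    ok = profile.populated & np.isfinite(profile.se) & (profile.se > 0)
    x = profile.centers[ok]
    y = profile.values[ok]
    w = 1.0 / profile.se[ok] ** 2
    if x.size < 3:
        raise EstimationError("need at least 3 populated bins for the angle fit")
    sxx = np.sum(w * x * x)
    if sxx <= 0:
        raise EstimationError("degenerate spread of phi bins")
    slope = np.sum(w * x * y) / sxx
    slope_se = 1.0 / np.sqrt(sxx)
    return AngleDriftModel(slope=float(slope), slope_se=float(slope_se), dt=float(dt))


class PiecewiseLinearDriftRegressor(BaseEstimator, RegressorMixin):
    """Continuous piecewise-linear weighted least squares with knot grid search.

    scikit-learn style: ``fit(x, y, sample_weight)`` with 1-D ``x``, then
    ``predict(x)``.  The knot grid defaults to the interior sample locations;
    ties in the weighted SSE are broken toward the lower knot(s).

    Parameters
    ----------
    n_pieces : {2, 3}
        Number of linear pieces (1 or 2 changepoints).
    min_side : int
        Minimum number of samples strictly on each side of every knot.

    Attributes
    ----------
    knots_ : ndarray of shape (n_pieces - 1,)
    slopes_ : ndarray of shape (n_pieces,)
    value0_ : float
        Fitted value at x = 0.
    sse_ : float
        Weighted sum of squared residuals at the optimum.
    drift_ : PiecewiseLinearDrift
        The fitted drift function.
    v_star_ : float
        Downward zero crossing of the fitted drift (preferred speed).
    """

    def __init__(self, n_pieces: int = 2, min_side: int = 2, require_root: bool = True):
        self.n_pieces = n_pieces
        self.min_side = min_side
        self.require_root = require_root

    @staticmethod
    def _design(x, knots):
        cols = [np.ones_like(x), x]
        cols.extend(np.maximum(x - k, 0.0) for k in knots)
        return np.column_stack(cols)

    def fit(self, x, y, sample_weight=None):
        if self.n_pieces not in (2, 3):
            raise ValueError("n_pieces must be 2 or 3")
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if sample_weight is None:
            w = np.ones_like(x)
        else:
            w = np.asarray(sample_weight, dtype=float).ravel()
        ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(w) & (w > 0)
        x, y, w = x[ok], y[ok], w[ok]
        order = np.argsort(x)
        x, y, w = x[order], y[order], w[order]
        n_knots = self.n_pieces - 1
        if x.size < self.n_pieces + 2:
            raise EstimationError(
                f"need at least {self.n_pieces + 2} populated bins for a "
                f"{self.n_pieces}-piece fit"
            )
        sw = np.sqrt(w)
        grid = x[self.min_side : x.size - self.min_side]
        if grid.size < n_knots:
            raise EstimationError("not enough interior points for the knot grid")

        def solve(knots):
            A = self._design(x, knots) * sw[:, None]
            beta, _, rank, _ = np.linalg.lstsq(A, y * sw, rcond=None)
            if rank < A.shape[1]:
                return None, np.inf
            resid = y * sw - A @ beta
            return beta, float(resid @ resid)

        best = (np.inf, None, None)
        if n_knots == 1:
            candidates = ((float(k),) for k in grid)
        else:
            candidates = (
                (float(grid[i]), float(grid[j]))
                for i in range(grid.size)
                for j in range(i + self.min_side, grid.size)
            )
        for knots in candidates:
            if len(set(knots)) < len(knots):
                continue
            beta, sse = solve(knots)
            # strict < keeps the lowest knot(s) on ties
            if beta is not None and sse < best[0]:
                best = (sse, knots, beta)
        if best[1] is None:
            raise EstimationError("piecewise fit failed on every candidate knot set")
        sse, knots, beta = best
        slopes = [beta[1]]
        for j in range(n_knots):
            slopes.append(slopes[-1] + beta[2 + j])
        self.knots_ = np.asarray(knots)
        self.slopes_ = np.asarray(slopes)
        self.value0_ = float(beta[0])
        self.sse_ = sse
        self.drift_ = PiecewiseLinearDrift(
            knots=tuple(knots), slopes=tuple(slopes), value0=float(beta[0])
        )
        if self.require_root:
            self.v_star_ = self.drift_.v_star  # raises if no downward crossing
        else:
            try:
                self.v_star_ = self.drift_.v_star
            except ValueError:
                self.v_star_ = np.nan
        return self

    def predict(self, x):
        return self.drift_(np.asarray(x, dtype=float))


def fit_speed_drift(profile: DriftProfile, n_pieces: int = 2) -> PiecewiseLinearDrift:
    """Fit a continuous piecewise-linear drift to the speed-drift profile.

    Weighted least squares (weights 1/SE^2) with changepoints grid-searched
    over the interior populated bin centers; raises
    :class:`~beeflight.models.PiecewiseLinearDrift`-level errors if the fitted
    drift has no downward zero crossing (no stable fixed point).
    """
    ok = profile.populated & np.isfinite(profile.se) & (profile.se > 0)
    reg = PiecewiseLinearDriftRegressor(n_pieces=n_pieces)
    reg.fit(profile.centers[ok], profile.values[ok], 1.0 / profile.se[ok] ** 2)
    return reg.drift_


def quantization_bias_correction(
    profile: DriftProfile,
    delta: float,
    mean_cos_phi: float,
    speed_variance: float,
    v_mean: float,
    dt: float | None = None,
) -> DriftProfile:
    """Remove the spurious drift slope induced by position quantization.

    Measured speeds share the rounding error of the middle position with the
    next increment, so the binned conditional mean acquires an approximately
    linear artifact with per-step slope ``Cov(Delta u, u)/Var(v_measured)``
    where ``Cov = -(2 + E[cos phi]) delta^2 / (12 dt^2)``.  The returned
    profile has the corresponding line (through the mean speed) subtracted.
    Knot locations and the attenuation of genuine slopes by the measurement
    error (a ~``Var(u)/Var(v)`` relative effect) are not touched.
    """
    dt = profile.dt if dt is None else dt
    if delta <= 0:
        return profile
    s2 = delta**2 / 12.0
    cov = -(2.0 + mean_cos_phi) * s2 / dt**2
    bias_slope = cov / (speed_variance * dt)
    return DriftProfile(
        centers=profile.centers,
        values=profile.values - bias_slope * (profile.centers - v_mean),
        se=profile.se,
        counts=profile.counts,
        axis=profile.axis,
        dt=profile.dt,
    )


def markov_bias_correction(
    profile: DriftProfile,
    drift: PiecewiseLinearDrift,
    noise_acf: AcfModel,
    noise_var: float,
    v_mean: float,
    v_var: float,
    dt: float | None = None,
    max_lag: int = 200,
) -> DriftProfile:
    """Remove the finite-correlation-time bias from a speed-drift profile.

    The conditional-moment estimator assumes Markovian dynamics; with
    correlated noise the state ``v_n`` and the upcoming noise ``xi_n`` are
    correlated, adding an approximately linear spurious term per drift piece,

        bias_i(v) ~ Cov_i / Var(v) * (v - anchor) / dt,
        Cov_i = sigma^2 * sum_{j>=0} a_i^j rho(j+1),

    where ``a_i = 1 + slope_i*dt`` is the one-step relaxation factor of piece
    ``i`` (speeds in a slowly relaxing regime remember the noise further
    back) and ``rho`` the fitted noise ACF.  The spurious term is assembled
    as a continuous piecewise-linear function on the same knots, anchored to
    vanish at the mean speed, and subtracted; refit the result to obtain
    corrected slopes and fixed point.  Changepoint locations are unaffected
    (the correction has no new kinks at other positions).
    """
    dt = profile.dt if dt is None else dt
    if noise_acf.family == "white":
        return profile
    slopes = np.asarray(drift.slopes)
    rho = noise_acf.normalized()
    lags = dt * np.arange(1, max_lag + 1)
    j = np.arange(max_lag)
    bias_slopes = []
    for s_i in slopes:
        a_i = float(np.clip(1.0 + s_i * dt, 0.0, 0.999999))
        cov = noise_var * float(np.sum(a_i**j * rho(lags)))
        bias_slopes.append(cov / (v_var * dt))
    bias = PiecewiseLinearDrift(
        knots=drift.knots, slopes=tuple(bias_slopes), value0=0.0
    )
    corrected = profile.values - (bias(profile.centers) - bias(v_mean))
    return DriftProfile(
        centers=profile.centers,
        values=corrected,
        se=profile.se,
        counts=profile.counts,
        axis=profile.axis,
        dt=profile.dt,
    )
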