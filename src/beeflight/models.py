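"""Parametric model components shared by estimation and simulation.

The reduced flight model draws, at each step of length ``dt``:

* a turning angle ``phi_n = wrap(sigma_phi(v_n) * g_n)`` with ``g`` a
  unit-variance (possibly correlated) Gaussian sequence, and
* a speed increment ``v_{n+1} = max(0, v_n + h_v(v_n)*dt + xi_n)`` with
  ``xi`` a Gaussian per-step noise of SD ``sigma`` and prescribed ACF.

``h_v`` is piecewise linear with a stable fixed point ``v_star`` (the
preferred flight speed); ``sigma_phi(v)`` decays with speed to a positive
offset (a shifted exponential or shifted power law).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PiecewiseLinearDrift",
    "AngleNoiseSigma",
    "AcfModel",
    "SpeedNoiseSpec",
    "ModelConfig",
    "default_model",
    "three_piece_model",
]


@dataclass(frozen=True)
class PiecewiseLinearDrift:
    """Continuous piecewise-linear speed drift ``h_v(v)`` in m/s^2.

    Parameters
    ----------
    knots : tuple of float
        Interior breakpoints (m/s), strictly increasing, length 1 or 2
        (two- or three-piece drift).
    slopes : tuple of float
        Slope of each piece (1/s); one more entry than ``knots``.
    value0 : float
        Drift at ``v = 0`` (m/s^2); continuity fixes the rest.
    """

    knots: tuple
    slopes: tuple
    value0: float

    def __post_init__(self):
        knots = tuple(float(k) for k in self.knots)
        slopes = tuple(float(s) for s in self.slopes)
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "slopes", slopes)
        if len(slopes) != len(knots) + 1:
            raise ValueError("need len(slopes) == len(knots) + 1")
        if any(k <= 0 for k in knots) or any(np.diff(knots) <= 0):
            raise ValueError("knots must be positive and strictly increasing")

    @classmethod
    def from_rates(cls, v_star: float, rates, knots=()) -> "PiecewiseLinearDrift":
        """Build from restoring rates: ``h_v(v) = rate_i * (v_star - v)`` form.

        ``rates`` (1/s, positive for a stable fixed point) give one slope
        ``-rate_i`` per piece; pieces are delimited by ``v_star`` itself and
        any additional ``knots`` above it.
        """
        all_knots = tuple(sorted({float(v_star), *map(float, knots)}))
        rates = tuple(float(r) for r in rates)
        slopes = tuple(-r for r in rates)
        if len(slopes) != len(all_knots) + 1:
            raise ValueError("need one rate per piece (len(knots) + 1)")
        # anchor the fixed point: value at v_star is 0
        drift = cls(knots=all_knots, slopes=slopes, value0=0.0)
        shift = drift(v_star)
        return cls(knots=all_knots, slopes=slopes, value0=-shift)

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        edges = np.concatenate([[0.0], np.asarray(self.knots)])
        vals = [self.value0]
        for i in range(len(self.knots)):
            vals.append(vals[-1] + self.slopes[i] * (edges[i + 1] - edges[i]))
        piece = np.searchsorted(np.asarray(self.knots), v, side="right")
        out = np.take(vals, piece) + np.take(self.slopes, piece) * (
            v - np.take(edges, piece)
        )
        return float(out) if out.ndim == 0 else out

    @property
    def v_star(self) -> float:
        """Stable fixed point: the downward zero-crossing of the drift."""
        grid = np.concatenate([[0.0], np.asarray(self.knots), [max(self.knots) * 4 + 1]])
        vals = self(grid)
        for i in range(len(grid) - 1):
            a, b = vals[i], vals[i + 1]
            if a == 0.0 and self.slopes[i] < 0:
                return float(grid[i])
            if a > 0 >= b or (a >= 0 > b):
                s = self.slopes[i]
                if s < 0:
                    return float(grid[i] - a / s)
        raise ValueError("drift has no stable fixed point (no downward sign change)")


@dataclass(frozen=True)
class AngleNoiseSigma:
    """Speed-dependent turning-angle noise SD ``sigma_phi(v)`` (rad).

    ``shifted_exponential``: ``a * exp(-v/b) + c`` with scale ``b`` in m/s.
    ``shifted_powerlaw``: ``a * max(v, v_floor)**(-b) + c`` with dimensionless
    exponent ``b``; the floor keeps the law finite as ``v -> 0``.
    """

    family: str = "shifted_exponential"
    a: float = 0.7
    b: float = 0.15
    c: float = 0.35
    v_floor: float = 0.01

    def __post_init__(self):
        if self.family not in ("shifted_exponential", "shifted_powerlaw"):
            raise ValueError(f"unknown sigma family {self.family!r}")
        if self.a < 0 or self.b <= 0 or self.c < 0:
            raise ValueError("need a >= 0, b > 0, c >= 0")
        # a = c = 0 is the degenerate noiseless limit (deterministic skeleton)

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        if self.family == "shifted_exponential":
            out = self.a * np.exp(-v / self.b) + self.c
        else:
            out = self.a * np.maximum(v, self.v_floor) ** (-self.b) + self.c
        return float(out) if out.ndim == 0 else out


# ACF family parameter names, in the order used for fitting.
_ACF_PARAMS = {
    "white": (),
    "exponential": ("c", "tau1"),
    "powerlaw": ("c", "kappa"),
    "diff_two_exponentials": ("c1", "tau1", "c2", "tau2"),
    "diff_two_powerlaws": ("c1", "kappa1", "c2", "kappa2"),
    "diff_exp_powerlaw": ("c1", "tau1", "c2", "kappa"),
}


@dataclass(frozen=True)
class AcfModel:
    """Parametric autocorrelation model, evaluated at lag times in seconds.

    Families (``tau`` = lag in s, ``dt`` = sampling step):

    * ``white``: 1 at lag 0, else 0.
    * ``exponential``: ``c * exp(-tau/tau1)``
    * ``powerlaw``: ``c * (1 + tau/dt)**(-kappa)`` (1-shifted so lag 0 is finite)
    * ``diff_two_exponentials``: ``c1*exp(-tau/tau1) - c2*exp(-tau/tau2)``
    * ``diff_two_powerlaws``: ``c1*(1+tau/dt)**(-kappa1) - c2*(1+tau/dt)**(-kappa2)``
    * ``diff_exp_powerlaw``: ``c1*exp(-tau/tau1) - c2*(1+tau/dt)**(-kappa)``

    The difference families can express the short-range anti-correlation seen
    in the speed noise: a fast positive component minus a slower one.
    """

    family: str
    params: dict = field(default_factory=dict)
    dt: float = 0.02

    def __post_init__(self):
        if self.family not in _ACF_PARAMS:
            raise ValueError(f"unknown ACF family {self.family!r}")
        names = _ACF_PARAMS[self.family]
        missing = set(names) - set(self.params)
        if missing:
            raise ValueError(f"family {self.family!r} missing params {sorted(missing)}")
        object.__setattr__(
            self, "params", {k: float(self.params[k]) for k in names}
        )
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    def __call__(self, tau):
        tau = np.asarray(tau, dtype=float)
        p = self.params
        if self.family == "white":
            out = np.where(tau == 0.0, 1.0, 0.0)
        elif self.family == "exponential":
            out = p["c"] * np.exp(-tau / p["tau1"])
        elif self.family == "powerlaw":
            out = p["c"] * (1.0 + tau / self.dt) ** (-p["kappa"])
        elif self.family == "diff_two_exponentials":
            out = p["c1"] * np.exp(-tau / p["tau1"]) - p["c2"] * np.exp(-tau / p["tau2"])
        elif self.family == "diff_two_powerlaws":
            base = 1.0 + tau / self.dt
            out = p["c1"] * base ** (-p["kappa1"]) - p["c2"] * base ** (-p["kappa2"])
        else:  # diff_exp_powerlaw
            out = p["c1"] * np.exp(-tau / p["tau1"]) - p["c2"] * (
                1.0 + tau / self.dt
            ) ** (-p["kappa"])
        return float(out) if out.ndim == 0 else out

    @property
    def value0(self) -> float:
        return float(self(0.0))

    def normalized(self) -> "AcfModel":
        """Rescale amplitudes so the model equals 1 at lag 0."""
        v0 = self.value0
        if v0 == 0:
            raise ValueError("cannot normalize an ACF that vanishes at lag 0")
        if math.isclose(v0, 1.0, rel_tol=1e-12):
            return self
        scaled = dict(self.params)
        for k in scaled:
            if k.startswith("c"):
                scaled[k] = scaled[k] / v0
        return AcfModel(self.family, scaled, self.dt)

    @property
    def timescales(self) -> tuple:
        """Sorted e-folding timescales (s) of the exponential components."""
        return tuple(sorted(v for k, v in self.params.items() if k.startswith("tau")))


@dataclass(frozen=True)
class SpeedNoiseSpec:
    """Marginal SD (m/s per step, after discretization correction) and ACF of xi_v."""

    sigma: float
    acf: AcfModel

    def __post_init__(self):
        if not self.sigma >= 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to simulate the reduced flight model."""

    dt: float
    speed_drift: PiecewiseLinearDrift
    angle_sigma: AngleNoiseSigma
    angle_acf: AcfModel
    speed_noise: SpeedNoiseSpec
    v_init: float = None  # type: ignore[assignment]
    theta_init: float = 0.0
    origin: tuple = (0.0, 0.0)

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.v_init is None:
            object.__setattr__(self, "v_init", self.speed_drift.v_star)
        if self.v_init < 0:
            raise ValueError("v_init must be non-negative")
        object.__setattr__(self, "origin", tuple(map(float, self.origin)))

    # ----- flat dict serialization (round-trips through YAML) -----

    def to_dict(self) -> dict:
        return {
            "dt": self.dt,
            "speed_drift": {
                "knots": list(self.speed_drift.knots),
                "slopes": list(self.speed_drift.slopes),
                "value0": self.speed_drift.value0,
            },
            "angle_sigma": {
                "family": self.angle_sigma.family,
                "a": self.angle_sigma.a,
                "b": self.angle_sigma.b,
                "c": self.angle_sigma.c,
                "v_floor": self.angle_sigma.v_floor,
            },
            "angle_acf": {
                "family": self.angle_acf.family,
                "params": dict(self.angle_acf.params),
            },
            "speed_noise": {
                "sigma": self.speed_noise.sigma,
                "acf": {
                    "family": self.speed_noise.acf.family,
                    "params": dict(self.speed_noise.acf.params),
                },
            },
            "v_init": self.v_init,
            "theta_init": self.theta_init,
            "origin": list(self.origin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        dt = float(d["dt"])
        return cls(
            dt=dt,
            speed_drift=PiecewiseLinearDrift(
                knots=tuple(d["speed_drift"]["knots"]),
                slopes=tuple(d["speed_drift"]["slopes"]),
                value0=float(d["speed_drift"]["value0"]),
            ),
            angle_sigma=AngleNoiseSigma(**d["angle_sigma"]),
            angle_acf=AcfModel(
                d["angle_acf"]["family"], dict(d["angle_acf"]["params"]), dt
            ),
            speed_noise=SpeedNoiseSpec(
                sigma=float(d["speed_noise"]["sigma"]),
                acf=AcfModel(
                    d["speed_noise"]["acf"]["family"],
                    dict(d["speed_noise"]["acf"]["params"]),
                    dt,
                ),
            ),
            v_init=float(d["v_init"]),
            theta_init=float(d["theta_init"]),
            origin=tuple(d["origin"]),
        )


def default_model(dt: float = 0.02) -> ModelConfig:
    """Default flight model: two-piece drift with fixed point at 0.27 m/s.

    The restoring rate below the preferred speed (5 /s) exceeds the one above
    (1 /s): a slow bee accelerates briskly, a fast one is in no hurry to give
    up speed.  Turning-angle noise is uncorrelated step to step with a
    speed-dependent SD decaying to a positive offset; speed noise is mildly
    anti-correlated over a few steps (difference of exponentials with a
    sub-step fast component).
    """
    return ModelConfig(
        dt=dt,
        speed_drift=PiecewiseLinearDrift.from_rates(0.27, rates=(5.0, 1.0)),
        angle_sigma=AngleNoiseSigma("shifted_exponential", a=0.7, b=0.15, c=0.35),
        angle_acf=AcfModel("white", {}, dt),
        speed_noise=SpeedNoiseSpec(
            sigma=0.025,
            acf=AcfModel(
                "diff_two_exponentials",
                {"c1": 1.1, "tau1": 0.01, "c2": 0.1, "tau2": 0.06},
                dt,
            ),
        ),
    )


def three_piece_model(dt: float = 0.02) -> ModelConfig:
    """Three-piece drift variant: an extra knot at 0.55 m/s with a steeper
    outer slope, modelling the stronger deceleration at rare very high speeds."""
    base = default_model(dt)
    return ModelConfig(
        dt=dt,
        speed_drift=PiecewiseLinearDrift.from_rates(
            0.27, rates=(5.0, 1.0, 4.0), knots=(0.55,)
        ),
        angle_sigma=base.angle_sigma,
        angle_acf=base.angle_acf,
        speed_noise=base.speed_noise,
    )
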