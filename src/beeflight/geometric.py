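"""Closed-form geometric null model for speed-dependent turning angles.

If the velocity changes each step by an isotropic i.i.d. Gaussian
acceleration (per-axis SD ``sigma_a``) added to the previous velocity of
magnitude ``v``, the turning angle is the direction of the offset Gaussian
vector ``(R + a_x, a_y)`` with ``R = v / sigma_a`` and standard-normal
``a_x, a_y`` — the projected-normal (offset isotropic Gaussian) angle
distribution:

    p(phi) = (1/2pi) exp(-R^2/2) [1 + q sqrt(2 pi) Phi(q) exp(q^2/2)],
    q = R cos(phi),

with ``Phi`` the standard normal CDF.  At ``R = 0`` this is uniform on the
circle; for large ``R`` it concentrates at 0 with SD ~ 1/R.  Real flight data
whose angle-noise SD decays to a *positive* offset therefore cannot come from
speed-independent accelerations — the motivation for the shifted
sigma_phi(v) families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import norm

__all__ = [
    "GeometricAngleParams",
    "geometric_angle_pdf",
    "geometric_angle_circstd",
    "sample_geometric_angles",
]


@dataclass(frozen=True)
class GeometricAngleParams:
    """Speed-to-noise ratio R = previous speed / per-axis acceleration SD."""

    R: float

    def __post_init__(self):
        if not self.R >= 0:
            raise ValueError("R must be non-negative")


def _as_R(params) -> float:
    return params.R if isinstance(params, GeometricAngleParams) else float(params)


def geometric_angle_pdf(phi, params) -> np.ndarray:
    """Density (1/rad) of the turning angle under the geometric null model.

    Symmetric in phi and normalized over (-pi, pi].
    """
    R = _as_R(params)
    phi = np.asarray(phi, dtype=float)
    q = R * np.cos(phi)
    # q*Phi(q)*exp(q^2/2) overflows for large positive q; use the stable split
    # exp(-R^2/2 + q^2/2) = exp(-(R sin phi)^2 / 2)
    base = np.exp(-0.5 * R * R) / (2.0 * np.pi)
    tail = (
        q
        * np.sqrt(2.0 * np.pi)
        * norm.cdf(q)
        * np.exp(-0.5 * (R * np.sin(phi)) ** 2)
        / (2.0 * np.pi)
    )
    out = base + tail
    return float(out) if out.ndim == 0 else out


def geometric_angle_circstd(params) -> float:
    """SD of the turning angle over (-pi, pi] by numerical quadrature.

    The mean is 0 by symmetry, so this is ``sqrt(int phi^2 p(phi) dphi)``.
    At R = 0 it equals pi/sqrt(3) (uniform); it decays like 1/R for large R.
    """
    R = _as_R(params)
    w = 1.0 / max(R, 1.0)  # help the quadrature find the sharp peak at 0
    val, err = integrate.quad(
        lambda p: p * p * geometric_angle_pdf(p, R),
        -np.pi,
        np.pi,
        limit=200,
        points=[-w, 0.0, w],
    )
    if not np.isfinite(val) or val < 0 or err > 1e-6 * max(val, 1e-12) + 1e-10:
        raise ArithmeticError("quadrature for the angle variance failed")
    return float(np.sqrt(val))


def sample_geometric_angles(params, n: int, seed: int = 0) -> np.ndarray:
    """Monte-Carlo oracle: angles of ``(R + a_x, a_y)`` for standard-normal pairs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    R = _as_R(params)
    rng = np.random.default_rng(seed)
    ax = rng.standard_normal(n)
    ay = rng.standard_normal(n)
    return np.arctan2(ay, R + ax)
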