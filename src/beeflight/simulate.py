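"""Euler-Maruyama simulation of the reduced flight model.

Correlated unit-variance Gaussian noise for the turning angle and correlated
speed noise (SD in m/s per step) are pre-generated spectrally; the iteration
is then

    phi_n     = wrap(sigma_phi(v_n) * g_n)
    theta_n+1 = wrap(theta_n + phi_n)
    v_n+1     = max(0, v_n + h_v(v_n) * dt + xi_n)
    r_n+1     = r_n + v_n * dt * (cos theta_n, sin theta_n)

The ``max(0, .)`` clamp enforces non-negative speed in the rare draws where
the Gaussian noise would overwhelm the positive low-speed drift; activations
are counted.  Scaling the correlated angle noise by sigma_phi(v_n) at each
step means the realized turning-angle ACF only approximates the configured
one; the error is small compared to estimation error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colored import ColoredNoiseRequest, generate_colored_gaussian
from .models import ModelConfig
from .noise import AcfEstimate, estimate_acf
from .trajectories import KinematicSeries, Trajectory, wrap_angle

__all__ = ["SimOutput", "simulate", "stationary_summaries", "StationarySummary"]


@dataclass
class SimOutput:
    """Simulated trajectory plus the kinematics it was built from."""

    trajectory: Trajectory
    kinematics: KinematicSeries
    clamp_count: int
    seed: int


def _speed_path(v0, drift_knots, drift_slopes, drift_value0, dt, xi):
    """Sequential speed update with non-negativity clamp (pure-python loop)."""
    n = xi.size
    v = np.empty(n + 1)
    v[0] = v0
    knots = tuple(drift_knots)
    slopes = tuple(drift_slopes)
    # precompute per-piece (intercept, slope) of h(v)*dt
    edges = (0.0,) + knots
    vals = [drift_value0]
    for i in range(len(knots)):
        vals.append(vals[-1] + slopes[i] * (edges[i + 1] - edges[i]))
    lin = [
        ((vals[i] - slopes[i] * edges[i]) * dt, slopes[i] * dt)
        for i in range(len(slopes))
    ]
    clamps = 0
    cur = float(v0)
    if len(knots) == 1:
        k0 = knots[0]
        (a0, b0), (a1, b1) = lin
        for i in range(n):
            if cur <= k0:
                nxt = cur + a0 + b0 * cur + xi[i]
            else:
                nxt = cur + a1 + b1 * cur + xi[i]
            if nxt < 0.0:
                nxt = 0.0
                clamps += 1
            v[i + 1] = nxt
            cur = nxt
    else:
        k0, k1 = knots
        (a0, b0), (a1, b1), (a2, b2) = lin
        for i in range(n):
            if cur <= k0:
                nxt = cur + a0 + b0 * cur + xi[i]
            elif cur <= k1:
                nxt = cur + a1 + b1 * cur + xi[i]
            else:
                nxt = cur + a2 + b2 * cur + xi[i]
            if nxt < 0.0:
                nxt = 0.0
                clamps += 1
            v[i + 1] = nxt
            cur = nxt
    return v, clamps


def simulate(config: ModelConfig, n_steps: int, seed: int = 0) -> SimOutput:
    """Simulate ``n_steps`` steps of the reduced model; deterministic per seed.

    Returns ``n_steps + 1`` positions, ``n_steps`` speeds/headings and
    ``n_steps - 1`` turning angles.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if not isinstance(config, ModelConfig):
        raise TypeError("config must be a ModelConfig")
    dt = config.dt
    ss = np.random.SeedSequence(seed)
    seed_v, seed_phi = (
        int(s.generate_state(1, np.uint64)[0] % (2**31)) for s in ss.spawn(2)
    )

    if config.speed_noise.sigma == 0:
        xi = np.zeros(n_steps - 1)  # deterministic skeleton
    else:
        xi = generate_colored_gaussian(
            ColoredNoiseRequest(
                n=max(n_steps - 1, 2),
                dt=dt,
                acf=config.speed_noise.acf,
                marginal_sd=config.speed_noise.sigma,
                seed=seed_v,
            )
        )[: n_steps - 1]
    g = generate_colored_gaussian(
        ColoredNoiseRequest(
            n=max(n_steps - 1, 2), dt=dt, acf=config.angle_acf, marginal_sd=1.0,
            seed=seed_phi,
        )
    )[: n_steps - 1]

    d = config.speed_drift
    v, clamps = _speed_path(config.v_init, d.knots, d.slopes, d.value0, dt, xi)
    # v has n_steps entries (v_0..v_{n_steps-1})
    sigma = config.angle_sigma(v[:-1])
    phi = wrap_angle(sigma * g)
    theta = wrap_angle(config.theta_init + np.concatenate([[0.0], np.cumsum(phi)]))
    x = config.origin[0] + np.concatenate([[0.0], np.cumsum(v * dt * np.cos(theta))])
    y = config.origin[1] + np.concatenate([[0.0], np.cumsum(v * dt * np.sin(theta))])
    traj = Trajectory(id=f"sim-{seed}", dt=dt, x=x, y=y)
    kin = KinematicSeries(dt=dt, v=v, theta=theta, phi=phi)
    return SimOutput(trajectory=traj, kinematics=kin, clamp_count=clamps, seed=seed)


@dataclass
class StationarySummary:
    """Post-burn-in empirical summaries of a simulated run."""

    speed_edges: np.ndarray
    speed_density: np.ndarray
    speed_acf: AcfEstimate
    angle_acf: AcfEstimate
    n_used: int


def stationary_summaries(
    output: SimOutput,
    burn_in: int | None = None,
    max_lag: int = 50,
    speed_edges=None,
) -> StationarySummary:
    """Speed density and speed/turning-angle ACFs after discarding a burn-in.

    ``burn_in`` defaults to 10% of the run (fixed-point relaxation is fast).
    """
    kin = output.kinematics
    n = len(kin)
    if burn_in is None:
        burn_in = n // 10
    if n - burn_in < 100:
        raise ValueError("insufficient post-burn-in length")
    v = kin.v[burn_in:]
    phi = kin.phi[burn_in:]
    if speed_edges is None:
        top = max(0.8, float(v.max()) + 0.02)
        speed_edges = np.arange(0.0, top + 0.01, 0.02)
    dens, edges = np.histogram(v, bins=speed_edges, density=True)
    lag = min(max_lag, v.size // 4)
    return StationarySummary(
        speed_edges=np.asarray(edges),
        speed_density=dens,
        speed_acf=estimate_acf(v, lag, dt=kin.dt),
        angle_acf=estimate_acf(phi, min(lag, phi.size // 4), dt=kin.dt),
        n_used=v.size,
    )
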