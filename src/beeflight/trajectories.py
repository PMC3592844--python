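"""Trajectory containers, tabular I/O, kinematics, gap handling and zone exclusion.

A trajectory is one contiguous planar track sampled at a fixed interval ``dt``.
Missing samples (tracking drop-outs, or samples excluded because they fall
inside a flower zone) are represented as NaN positions; all estimation code
requires gap-free segments, produced by :func:`split_and_filter`.

Angle conventions
-----------------
Headings ``theta`` are measured from the displacement vector of the step
starting at index ``n`` (forward difference); the turning angle
``phi_n = wrap(theta_{n+1} - theta_n)`` couples steps ``n`` and ``n+1``.
Positive ``phi`` is a counter-clockwise turn.  All angles live on the
half-open interval ``(-pi, pi]`` (so ``pi`` maps to ``pi``, not ``-pi``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "KinematicSeries",
    "GapSpec",
    "ZoneSet",
    "wrap_angle",
    "derive_kinematics",
    "interpolate_gaps",
    "split_and_filter",
    "read_trajectories",
    "write_trajectories",
    "EmptyDatasetError",
]


class EmptyDatasetError(ValueError):
    """Raised when filtering leaves no usable trajectory segment."""


def wrap_angle(angle):
    """Wrap an angle (rad) onto the half-open interval ``(-pi, pi]``.

    Accepts scalars or arrays.  Idempotent and 2*pi-periodic.

    >>> wrap_angle(2 * np.pi)
    0.0
    >>> wrap_angle(np.pi)
    3.141592653589793
    """
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("wrap_angle requires finite input")
    # reflect-wrap-reflect keeps +pi (instead of -pi) as the branch point
    wrapped = -(np.mod(-a + np.pi, 2.0 * np.pi) - np.pi)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass
class Trajectory:
    """One planar track at fixed sampling interval.

    Parameters
    ----------
    id : str
        Trajectory identifier.
    dt : float
        Sampling interval in seconds, > 0.
    t0 : float
        Time of the first sample in seconds.
    x, y : ndarray
        Positions in metres.  NaN marks a missing sample; fully observed
        trajectories must be finite everywhere.
    """

    id: str
    dt: float
    x: np.ndarray
    y: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1 or self.x.size != self.y.size:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.x.size < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if np.any(np.isinf(self.x)) or np.any(np.isinf(self.y)):
            raise ValueError("coordinates must not be infinite")

    def __len__(self) -> int:
        return self.x.size

    @property
    def t(self) -> np.ndarray:
        """Sample times ``t0 + n*dt``."""
        return self.t0 + self.dt * np.arange(len(self))

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of missing samples (NaN in either coordinate)."""
        return np.isnan(self.x) | np.isnan(self.y)

    @property
    def has_missing(self) -> bool:
        return bool(self.missing.any())

    def require_complete(self) -> "Trajectory":
        if self.has_missing:
            raise ValueError(f"trajectory {self.id!r} contains missing samples")
        return self


@dataclass
class KinematicSeries:
    """Per-step speed, heading and turning angle derived from a trajectory.

    ``v`` and ``theta`` have one entry per step (N-1 for N positions); ``phi``
    couples consecutive steps and is one shorter.  ``flagged`` marks steps with
    zero displacement whose heading was carried over from the previous step;
    flagged steps are excluded from drift and noise estimation.
    """

    dt: float
    v: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.flagged is None:
            self.flagged = np.zeros(self.theta.size, dtype=bool)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.v.size != self.theta.size or self.phi.size != self.v.size - 1:
            raise ValueError("need len(phi) = len(theta) - 1 = len(v) - 1")
        if np.any(self.v < 0):
            raise ValueError("speeds must be non-negative")

    def __len__(self) -> int:
        return self.v.size

    @property
    def valid_phi(self) -> np.ndarray:
        """Mask of phi entries not touching a flagged (zero-displacement) step."""
        return ~(self.flagged[:-1] | self.flagged[1:])


@dataclass(frozen=True)
class GapSpec:
    """Gap-handling policy: interpolate short tracking gaps, split at long ones."""

    max_interpolate: int = 2
    min_split: int = 5

    def __post_init__(self):
        if not (1 <= self.max_interpolate < self.min_split):
            raise ValueError("need 1 <= max_interpolate < min_split")


@dataclass(frozen=True)
class ZoneSet:
    """Circular exclusion zones (e.g. around flowers) of a common radius."""

    centers: tuple = ()
    radius: float = 0.05

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError("zone radius must be positive")
        object.__setattr__(
            self, "centers", tuple((float(cx), float(cy)) for cx, cy in self.centers)
        )

    def contains(self, x, y) -> np.ndarray:
        """Boolean mask of points within ``radius`` of any zone center."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = np.zeros(x.shape, dtype=bool)
        for cx, cy in self.centers:
            inside |= np.hypot(x - cx, y - cy) <= self.radius
        return inside


def derive_kinematics(traj: Trajectory) -> KinematicSeries:
    """Derive speed, heading and turning angle from positions.

    ``v_n = |r_{n+1} - r_n| / dt``, ``theta_n = atan2`` of the displacement,
    ``phi_n = wrap(theta_{n+1} - theta_n)``.  Zero-displacement steps (possible
    after position quantization) carry the previous heading forward and are
    flagged; a leading zero-displacement step takes the first defined heading.
    """
    traj.require_complete()
    if len(traj) < 3:
        raise ValueError("need at least 3 samples to derive kinematics")
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    disp = np.hypot(dx, dy)
    v = disp / traj.dt
    zero = disp == 0.0
    theta = np.arctan2(dy, dx)
    if zero.any():
        if zero.all():
            raise ValueError("all displacements vanish; heading undefined")
        # carry previous heading forward; back-fill a leading run
        idx = np.arange(theta.size)
        idx[zero] = -1
        idx = np.maximum.accumulate(idx)
        first = np.argmax(~zero)
        idx[idx < 0] = first
        theta = theta[idx]
    phi = wrap_angle(np.diff(theta))
    return KinematicSeries(dt=traj.dt, v=v, theta=theta, phi=phi, flagged=zero)


def _missing_runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of True-runs in a boolean mask."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for a, b in zip(edges[::2], edges[1::2]):
        yield int(a), int(b)


def interpolate_gaps(traj: Trajectory, spec: GapSpec) -> Trajectory:
    """Fill short runs of missing samples by linear interpolation.

    Runs of at most ``spec.max_interpolate`` missing samples flanked by
    observations on both sides are replaced by linear interpolation between the
    flanking positions; longer runs are left untouched.  Missing runs at either
    boundary cannot be interpolated and are truncated away.  Observed samples
    are never modified.
    """
    miss = traj.missing
    if not miss.any():
        return traj
    x = traj.x.copy()
    y = traj.y.copy()
    n = len(traj)
    for a, b in _missing_runs(miss):
        run = b - a
        if a == 0 or b == n or run > spec.max_interpolate:
            continue
        frac = np.arange(1, run + 1) / (run + 1)
        x[a:b] = x[a - 1] + frac * (x[b] - x[a - 1])
        y[a:b] = y[a - 1] + frac * (y[b] - y[a - 1])
    # truncate boundary gaps
    still = np.isnan(x) | np.isnan(y)
    lo, hi = 0, n
    if still[0]:
        lo = next(b for a, b in _missing_runs(still) if a == 0)
    if still[-1]:
        hi = next(a for a, b in _missing_runs(still) if b == n)
    if hi - lo < 2:
        raise EmptyDatasetError("trajectory empty after truncating boundary gaps")
    return Trajectory(
        id=traj.id, dt=traj.dt, t0=traj.t0 + lo * traj.dt, x=x[lo:hi], y=y[lo:hi]
    )


def split_and_filter(
    dataset: Iterable[Trajectory],
    spec: GapSpec,
    zones: ZoneSet | None = None,
    min_samples: int = 3,
) -> list[Trajectory]:
    """Remove in-zone samples, fill short gaps, split at the rest.

    In-zone samples are excluded outright (never interpolated: they were
    observed, just unwanted), so a zone crossing always splits a trajectory.
    Remaining tracking gaps of at most ``max_interpolate`` samples are linearly
    interpolated; any longer gap breaks the trajectory into contiguous
    segments, since a fixed-rate segment cannot carry an unfilled hole.
    Segments shorter than ``min_samples`` are dropped.

    Raises
    ------
    EmptyDatasetError
        If nothing survives the filtering.
    """
    out: list[Trajectory] = []
    for traj in dataset:
        in_zone = np.zeros(len(traj), dtype=bool)
        if zones is not None and zones.centers:
            obs = ~traj.missing
            in_zone[obs] = zones.contains(traj.x[obs], traj.y[obs])
        # hard-split at zone samples first so they cannot be interpolated over
        keep = ~in_zone
        seg_id = 0
        for a, b in _missing_runs(keep):
            if b - a < 2:
                continue
            piece = Trajectory(
                id=f"{traj.id}#{seg_id}" if (in_zone.any() or seg_id) else traj.id,
                dt=traj.dt,
                t0=traj.t0 + a * traj.dt,
                x=traj.x[a:b],
                y=traj.y[a:b],
            )
            seg_id += 1
            try:
                piece = interpolate_gaps(piece, spec)
            except EmptyDatasetError:
                continue
            # split at gaps that were too long to interpolate
            still = piece.missing
            if not still.any():
                segments = [piece]
            else:
                segments = []
                sub = 0
                for c, d in _missing_runs(~still):
                    if d - c < 2:
                        continue
                    segments.append(
                        Trajectory(
                            id=f"{piece.id}.{sub}",
                            dt=piece.dt,
                            t0=piece.t0 + c * piece.dt,
                            x=piece.x[c:d],
                            y=piece.y[c:d],
                        )
                    )
                    sub += 1
            out.extend(s for s in segments if len(s) >= min_samples)
    if not out:
        raise EmptyDatasetError("no usable segments after gap/zone filtering")
    return out


# ---------------------------------------------------------------------------
# Tabular I/O: comma-separated text with header traj_id,t,x,y (SI units).
# Missing samples appear either as absent rows (detected from the time stamps)
# or as rows with empty x/y fields.

_REL_DT_TOL = 1e-6


def read_trajectories(path, dt: float | None = None) -> list[Trajectory]:
    """Read trajectories from a ``traj_id,t,x,y`` CSV file.

    The sampling interval is inferred per trajectory (or forced via ``dt``);
    time stamps jittered by more than a relative ``1e-6`` of ``dt`` are
    rejected, and integer multiples of ``dt`` between consecutive rows are
    re-inserted as missing samples.
    """
    df = pd.read_csv(path)
    required = {"traj_id", "t", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory file needs columns {sorted(required)}")
    out = []
    for tid, g in df.groupby("traj_id", sort=False):
        t = g["t"].to_numpy(dtype=float)
        if t.size < 2:
            raise ValueError(f"trajectory {tid!r} has fewer than 2 rows")
        steps = np.diff(t)
        dt_use = float(dt) if dt is not None else float(np.min(steps))
        if dt_use <= 0:
            raise ValueError("non-increasing time stamps")
        ratio = steps / dt_use
        k = np.rint(ratio).astype(int)
        if np.any(k < 1) or np.any(np.abs(ratio - k) > _REL_DT_TOL * np.maximum(k, 1)):
            raise ValueError(
                f"trajectory {tid!r}: time stamps are not integer multiples of dt"
            )
        n = int(k.sum()) + 1
        x = np.full(n, np.nan)
        y = np.full(n, np.nan)
        pos = np.concatenate([[0], np.cumsum(k)])
        x[pos] = g["x"].to_numpy(dtype=float)
        y[pos] = g["y"].to_numpy(dtype=float)
        out.append(Trajectory(id=str(tid), dt=dt_use, t0=float(t[0]), x=x, y=y))
    return out


def write_trajectories(trajectories: Sequence[Trajectory], path) -> None:
    """Write trajectories in the same CSV dialect (missing samples as empty fields)."""
    frames = []
    for traj in trajectories:
        frames.append(
            pd.DataFrame(
                {"traj_id": traj.id, "t": traj.t, "x": traj.x, "y": traj.y}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
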