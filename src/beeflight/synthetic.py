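"""Ground-truth datasets: model trajectories through a camera-like observation model.

The observation model emulates the statistical artifacts of video tracking:
positions rounded to the camera's spatial resolution ``delta``, short random
tracking drop-outs, and samples removed inside exclusion zones.  Bundles carry
the generating :class:`~beeflight.models.ModelConfig` as recoverable truth, so
the whole estimation pipeline can be validated end to end without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .models import ModelConfig
from .simulate import simulate
from .trajectories import Trajectory, ZoneSet, read_trajectories, write_trajectories

__all__ = [
    "ObservationSpec",
    "GroundTruthBundle",
    "apply_observation_model",
    "make_ground_truth_dataset",
    "write_bundle",
    "read_bundle",
]


@dataclass(frozen=True)
class ObservationSpec:
    """Camera-like observation model.

    Parameters
    ----------
    delta : float
        Position quantization step (m); 0 disables quantization.  Default is
        the mm scale typical of a small-arena tracking camera.
    gap_rate : float
        Per-step probability of starting a tracking drop-out, < 0.1.
    gap_lengths : tuple of int
        Support of the (uniform) gap-length distribution, in steps.
    zones : ZoneSet or None
        Exclusion zones whose samples are marked missing.
    seed : int
        Seed for gap placement (quantization is deterministic).
    """

    delta: float = 0.0015
    gap_rate: float = 0.002
    gap_lengths: tuple = (1, 2, 3, 4)
    zones: ZoneSet | None = None
    seed: int = 0

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 0.0 <= self.gap_rate < 0.1:
            raise ValueError("gap_rate must be in [0, 0.1)")
        if self.gap_rate > 0 and not self.gap_lengths:
            raise ValueError("gap_lengths must be non-empty when gap_rate > 0")

    @classmethod
    def clean(cls) -> "ObservationSpec":
        """No quantization, no gaps, no zones."""
        return cls(delta=0.0, gap_rate=0.0)


@dataclass
class GroundTruthBundle:
    """Observed dataset + generating truth + pre-observation clean tracks."""

    dataset: list
    truth: ModelConfig
    clean: list
    obs: ObservationSpec
    seeds: list = field(default_factory=list)


def apply_observation_model(traj: Trajectory, spec: ObservationSpec) -> Trajectory:
    """Quantize positions, insert tracking gaps, mark in-zone samples missing.

    Deterministic given ``spec.seed``.
    """
    x = traj.x.copy()
    y = traj.y.copy()
    if spec.delta > 0:
        x = np.rint(x / spec.delta) * spec.delta
        y = np.rint(y / spec.delta) * spec.delta
    n = x.size
    miss = np.zeros(n, dtype=bool)
    if spec.gap_rate > 0:
        rng = np.random.default_rng(spec.seed)
        starts = np.flatnonzero(rng.random(n) < spec.gap_rate)
        lengths = rng.choice(np.asarray(spec.gap_lengths, dtype=int), size=starts.size)
        for s, ln in zip(starts, lengths):
            miss[s : s + ln] = True
    if spec.zones is not None and spec.zones.centers:
        miss |= spec.zones.contains(x, y)
    x[miss] = np.nan
    y[miss] = np.nan
    return Trajectory(id=traj.id, dt=traj.dt, t0=traj.t0, x=x, y=y)


def _child_seed(master: int, index: int) -> int:
    """Per-trajectory seed derived from the master seed; always < 2**31."""
    ss = np.random.SeedSequence([int(master), int(index)])
    return int(ss.generate_state(1, np.uint64)[0] % (2**31))


def make_ground_truth_dataset(
    config: ModelConfig,
    n_traj: int,
    steps_per_traj: int,
    obs: ObservationSpec | None = None,
    seed: int = 0,
) -> GroundTruthBundle:
    """Simulate independent trajectories and pass each through the observation model."""
    if n_traj < 1 or steps_per_traj < 2:
        raise ValueError("need n_traj >= 1 and steps_per_traj >= 2")
    obs = ObservationSpec.clean() if obs is None else obs
    clean, observed, seeds = [], [], []
    for i in range(n_traj):
        s = _child_seed(seed, i)
        seeds.append(s)
        out = simulate(config, steps_per_traj, seed=s)
        traj = replace(out.trajectory, id=f"gt-{i}")
        clean.append(traj)
        obs_i = ObservationSpec(
            delta=obs.delta,
            gap_rate=obs.gap_rate,
            gap_lengths=obs.gap_lengths,
            zones=obs.zones,
            seed=_child_seed(seed, n_traj + i),
        )
        observed.append(apply_observation_model(traj, obs_i))
    return GroundTruthBundle(
        dataset=observed, truth=config, clean=clean, obs=obs, seeds=seeds
    )


# ---------------------------------------------------------------------------
# bundle I/O: a directory with trajectory CSVs, the truth config and a manifest


def write_bundle(bundle: GroundTruthBundle, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_trajectories(bundle.dataset, d / "observed.csv")
    write_trajectories(bundle.clean, d / "clean.csv")
    with open(d / "truth.yaml", "w") as fh:
        yaml.safe_dump(bundle.truth.to_dict(), fh, sort_keys=True)
    manifest = {
        "seeds": [int(s) for s in bundle.seeds],
        "observation": {
            "delta": bundle.obs.delta,
            "gap_rate": bundle.obs.gap_rate,
            "gap_lengths": list(bundle.obs.gap_lengths),
            "seed": bundle.obs.seed,
        },
    }
    with open(d / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_bundle(directory) -> GroundTruthBundle:
    d = Path(directory)
    with open(d / "truth.yaml") as fh:
        truth = ModelConfig.from_dict(yaml.safe_load(fh))
    with open(d / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    obs = ObservationSpec(
        delta=float(manifest["observation"]["delta"]),
        gap_rate=float(manifest["observation"]["gap_rate"]),
        gap_lengths=tuple(manifest["observation"]["gap_lengths"]),
        seed=int(manifest["observation"]["seed"]),
    )
    return GroundTruthBundle(
        dataset=read_trajectories(d / "observed.csv", dt=truth.dt),
        truth=truth,
        clean=read_trajectories(d / "clean.csv", dt=truth.dt),
        obs=obs,
        seeds=[int(s) for s in manifest["seeds"]],
    )
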