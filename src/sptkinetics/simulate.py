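"""Synthetic two-state single-particle-tracking data.

Generates trajectories with the statistical structure that live-cell SPT of
nuclear proteins produces: a quasi-immobile chromatin-bound population and a
fast freely diffusing population, Gaussian localization error, geometric
(photobleaching-limited) track lifetimes, and loss of free molecules that
diffuse axially out of the microscope's finite detection slab.

Each molecule is assigned one state for its whole lifetime — the two-state
kinetic model fitted downstream has no bound/free exchange term, and the
generator matches that assumption. Free molecules diffuse in z with the same
coefficient as laterally; their track ends at the first passage of z to
either face of the detection slab (thickness ``dz``), evaluated in
continuous time via the per-step Brownian-bridge crossing probability, so
the axial loss process is exactly the absorbing-slab diffusion problem used
for the z-correction factor in the kinetic fit. Bound molecules ride on
chromatin and are treated as staying in focus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .tracks import Trajectory, TrajectorySet

__all__ = [
    "SimConfig",
    "simulate_trajectories",
    "simulate_localizations",
    "condition_preset",
    "CONDITION_PRESETS",
]


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the two-state diffusion model.

    Attributes
    ----------
    n_molecules
        Number of molecules to simulate.
    f_bound
        Probability that a molecule is chromatin-bound, in [0, 1].
    d_bound, d_free
        Diffusion coefficients of the bound and free states, µm²/s.
    sigma_loc
        Localization error SD per axis, µm (applied to observed positions only).
    dt
        Frame interval, s.
    dz
        Axial detection-slab thickness, µm.
    bleach_prob
        Per-frame photobleaching probability in [0, 1); track lifetimes are
        geometric with this parameter.
    roi
        Lateral field (width, height) in µm; bounds initial positions only.
    pixel_size
        Camera pixel size, µm (used by the linking stage's jump gate).
    min_track_len
        Minimum number of frames for a track to be kept, ≥ 2.
    max_frames
        Hard cap on track length (movie length), needed when bleach_prob = 0.
    seed
        Integer seed; one seed drives all randomness of a simulation.
    """

    n_molecules: int = 5000
    f_bound: float = 0.5
    d_bound: float = 0.03
    d_free: float = 1.0
    sigma_loc: float = 0.03
    dt: float = 0.010
    dz: float = 0.65
    bleach_prob: float = 0.1
    roi: tuple[float, float] = (12.8, 12.8)
    pixel_size: float = 0.107
    min_track_len: int = 3
    max_frames: int = 1000
    seed: int = 0
    condition_label: str = ""

    def __post_init__(self) -> None:
        checks = [
            ("n_molecules", self.n_molecules >= 1),
            ("f_bound", 0.0 <= self.f_bound <= 1.0),
            ("d_bound", self.d_bound >= 0.0),
            ("d_free", self.d_free >= 0.0),
            ("sigma_loc", self.sigma_loc >= 0.0),
            ("dt", self.dt > 0.0),
            ("dz", self.dz > 0.0),
            ("bleach_prob", 0.0 <= self.bleach_prob < 1.0),
            ("roi", len(self.roi) == 2 and all(r > 0 for r in self.roi)),
            ("pixel_size", self.pixel_size > 0.0),
            ("min_track_len", self.min_track_len >= 2),
            ("max_frames", self.max_frames >= self.min_track_len),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid SimConfig field: {name}")


def _track_lifetimes(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Number of frames each molecule would be observed absent axial loss."""
    if cfg.bleach_prob > 0.0:
        life = rng.geometric(cfg.bleach_prob, size=cfg.n_molecules)
        return np.minimum(life, cfg.max_frames)
    return np.full(cfg.n_molecules, cfg.max_frames, dtype=np.int64)


def _bridge_survival(z0: float, z1: float, s2: float, dz: float, k_images: int = 3) -> float:
    """P(Brownian bridge z0 -> z1, variance s2, stays inside (0, dz)).

    Image-series expansion; both endpoints must lie inside the slab. Terms
    decay like exp(-2 k² dz²/s2), so a few images suffice even when the step
    SD is a sizable fraction of the slab.
    """
    total = 0.0
    diff = z1 - z0
    for k in range(-k_images, k_images + 1):
        a = k * dz
        total += math.exp(-2.0 * a * (a + diff) / s2)
        total -= math.exp(-2.0 * (a + z0) * (a + z1) / s2)
    return min(max(total, 0.0), 1.0)


def _axial_survival_steps(
    rng: np.random.Generator, n_steps: int, d: float, dt: float, dz: float
) -> int:
    """Steps survived before first passage of z to the slab boundary.

    z starts uniform in (0, dz). Each frame interval advances z by a Gaussian
    step; absorption within the interval (even when both endpoints lie inside
    the slab) is drawn from the Brownian-bridge boundary-crossing probability,
    so the sampled first-passage time is the continuous-time one.
    """
    if d <= 0.0 or n_steps == 0:
        return n_steps
    s2 = 2.0 * d * dt  # per-step variance
    z = dz * rng.uniform()
    steps = rng.normal(0.0, math.sqrt(s2), size=n_steps)
    u = rng.uniform(size=n_steps)
    for i in range(n_steps):
        z1 = z + steps[i]
        if z1 <= 0.0 or z1 >= dz:
            return i
        if u[i] > _bridge_survival(z, z1, s2, dz):
            return i
        z = z1
    return n_steps


def simulate_trajectories(config: SimConfig) -> TrajectorySet:
    """Simulate observed two-state trajectories.

    Returns a :class:`TrajectorySet` whose provenance records the generative
    config and the ground-truth state of every surviving track
    (``provenance["bound"]``: track_id -> bool).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    bound = rng.uniform(size=cfg.n_molecules) < cfg.f_bound
    lifetimes = _track_lifetimes(rng, cfg)

    step_sd = {True: math.sqrt(2.0 * cfg.d_bound * cfg.dt),
               False: math.sqrt(2.0 * cfg.d_free * cfg.dt)}
    trajs: list[Trajectory] = []
    states: dict[int, bool] = {}
    for i in range(cfg.n_molecules):
        n_frames = int(lifetimes[i])
        if not bound[i]:
            surv = _axial_survival_steps(rng, n_frames - 1, cfg.d_free, cfg.dt, cfg.dz)
            n_frames = surv + 1
        if n_frames < 2:
            # draw-stream stability: nothing more to consume for this molecule
            continue
        x0 = cfg.roi[0] * rng.uniform()
        y0 = cfg.roi[1] * rng.uniform()
        sd = step_sd[bool(bound[i])]
        steps = rng.normal(0.0, sd, size=(n_frames - 1, 2)) if sd > 0 else np.zeros((n_frames - 1, 2))
        true_xy = np.empty((n_frames, 2))
        true_xy[0] = (x0, y0)
        np.cumsum(steps, axis=0, out=true_xy[1:])
        true_xy[1:] += (x0, y0)
        if cfg.sigma_loc > 0:
            obs = true_xy + rng.normal(0.0, cfg.sigma_loc, size=true_xy.shape)
        else:
            obs = true_xy
        if n_frames < cfg.min_track_len:
            continue
        trajs.append(
            Trajectory(track_id=i, frames=np.arange(n_frames), x=obs[:, 0], y=obs[:, 1])
        )
        states[i] = bool(bound[i])

    return TrajectorySet(
        trajectories=trajs,
        dt=cfg.dt,
        condition_label=cfg.condition_label,
        provenance={"config": cfg, "bound": states},
    )


def simulate_localizations(config: SimConfig) -> tuple[pd.DataFrame, TrajectorySet]:
    """Per-frame unlabeled detections plus the ground-truth track assignment.

    The ground truth is returned separately so a linking stage can be scored
    against it; the localization table itself carries no identity.
    """
    truth = simulate_trajectories(config)
    df = truth.to_frame()
    locs = (
        df[["frame", "x_um", "y_um"]]
        .sort_values(["frame", "x_um", "y_um"], kind="mergesort")
        .reset_index(drop=True)
    )
    return locs, truth


# Condition presets: generative parameters set to each condition's published
# two-state estimates (bound fraction and diffusion coefficients), with the
# detection-slab thickness of the dye used for that condition (0.65 µm for
# JF646, 0.60 µm for JF552). Free-state D was reported only for the histone
# fusions; for Swr1 (a ~1 MDa remodeling complex, slower than a free
# histone dimer) 1.0 µm²/s is used.
CONDITION_PRESETS: dict[str, dict] = {
    # wild-type histones, JF646
    "h2az_wt": dict(f_bound=0.82, d_bound=0.03, d_free=1.18, dz=0.65),
    "h2b_wt": dict(f_bound=0.76, d_bound=0.03, d_free=1.29, dz=0.65),
    # SWR1 remodeler (catalytic subunit) in wild type and the swc2 deletion
    "swr1_wt": dict(f_bound=0.47, d_bound=0.03, d_free=1.00, dz=0.65),
    "swr1_swc2del": dict(f_bound=0.21, d_bound=0.03, d_free=1.00, dz=0.65),
    # H2A.Z in the anchor-away background, JF552: untreated control, Swc5
    # depletion, and double depletions that block eviction
    "swc5_control": dict(f_bound=0.79, d_bound=0.03, d_free=1.18, dz=0.60),
    "swc5_aa": dict(f_bound=0.49, d_bound=0.03, d_free=1.18, dz=0.60),
    "swc5_rpb1_aa": dict(f_bound=0.66, d_bound=0.03, d_free=1.18, dz=0.60),
    "swc5_kin28_aa": dict(f_bound=0.65, d_bound=0.03, d_free=1.18, dz=0.60),
}


def condition_preset(name: str, **overrides) -> SimConfig:
    """Return the generative :class:`SimConfig` for a named experimental condition.

    ``overrides`` replace any SimConfig field (commonly ``n_molecules`` and
    ``seed``). Unknown names raise with the list of valid ones.
    """
    if name not in CONDITION_PRESETS:
        valid = ", ".join(sorted(CONDITION_PRESETS))
        raise KeyError(f"unknown condition preset {name!r}; valid presets: {valid}")
    params = dict(CONDITION_PRESETS[name])
    params.update(overrides)
    return SimConfig(condition_label=name, **params)
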