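import numpy as np
import pytest

from sptkinetics import SimConfig, Trajectory, TrajectorySet, simulate_trajectories


@pytest.fixture
def single_state_free_config():
    """Pure free population, no noise, no bleaching pressure beyond default."""
    return SimConfig(n_molecules=9000, f_bound=0.0, d_free=1.0, d_bound=0.0,
                     sigma_loc=0.0, dt=0.01, bleach_prob=0.1, seed=11)


@pytest.fixture
def bound_only_config():
    return SimConfig(n_molecules=3000, f_bound=1.0, d_bound=0.03, d_free=1.0,
                     sigma_loc=0.03, dt=0.01, bleach_prob=0.1, seed=12)


@pytest.fixture
def toy_trajectory():
    """Alternating 1 µm hops along x; MSD hand-enumerable."""
    return Trajectory(track_id=0, frames=np.arange(6),
                      x=np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0]),
                      y=np.zeros(6))


def mc_slab_survival(rng, n_walkers, dz, d, dt, n_steps):
    """Monte-Carlo absorbing-slab survival, uniform start, continuous time.

    Frame-sized Gaussian steps plus exact image-series Brownian-bridge
    absorption within each step; returns the survival fraction after each
    step. Independent oracle for the eigenfunction-series z correction.
    """
    z = dz * rng.uniform(size=n_walkers)
    alive = np.ones(n_walkers, bool)
    s2 = 2 * d * dt
    out = []
    for _ in range(n_steps):
        zn = z + rng.normal(0, np.sqrt(s2), n_walkers)
        surv = np.zeros(n_walkers)
        inside = (zn > 0) & (zn < dz)
        for k in range(-3, 4):
            a = k * dz
            surv += np.exp(-2 * a * (a + zn - z) / s2)
            surv -= np.exp(-2 * (a + z) * (a + zn) / s2)
        dead = ~inside | (rng.uniform(size=n_walkers) > np.clip(surv, 0, 1))
        alive &= ~dead
        z = np.where(alive, zn, z)
        out.append(alive.mean())
    return np.array(out)


def make_brownian_set(n_tracks: int, d: float, dt: float = 0.01, length: int = 20,
                      sigma: float = 0.0, seed: int = 0) -> TrajectorySet:
    """Plain single-state Brownian tracks of fixed length (no slab, no bleach)."""
    rng = np.random.default_rng(seed)
    sd = np.sqrt(2 * d * dt)
    trajs = []
    for i in range(n_tracks):
        steps = rng.normal(0, sd, size=(length - 1, 2))
        xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        if sigma > 0:
            xy = xy + rng.normal(0, sigma, size=xy.shape)
        trajs.append(Trajectory(track_id=i, frames=np.arange(length),
                                x=xy[:, 0], y=xy[:, 1]))
    return TrajectorySet(trajectories=trajs, dt=dt)
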