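"""Per-trajectory diffusion coefficients from MSD, and two-component
Gaussian decomposition of the log10 D distribution.

For a gapless track the time-averaged MSD at lag n is the mean of
(x_{i+n}−x_i)² + (y_{i+n}−y_i)² over all overlapping pairs. For 2D Brownian
motion MSD(nΔt) = 4·D·nΔt + 4σ², so an ordinary least-squares line over
lags 2–5 with a free intercept yields D = slope/4 with the localization
error absorbed into the intercept. Tracks are accepted when the fit has
R² > 0.8 and a positive slope (log D is undefined otherwise).

The accepted tracks' log10 D values form a bimodal distribution — a slow
chromatin-bound mode and a fast free mode — decomposed by a two-component
Gaussian mixture (maximum likelihood EM); the slow-component weight is the
MSD-based estimate of the chromatin-bound fraction. Standard errors come
from bootstrap resampling of tracks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .tracks import Trajectory, TrajectorySet

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "compute_msd",
    "estimate_d",
    "analyze_tracks",
    "log_d_distribution",
    "MixtureFit",
    "fit_mixture",
    "bootstrap_mixture",
]

logger = logging.getLogger(__name__)

R2_THRESHOLD = 0.8
FIT_LAGS = (2, 3, 4, 5)


@dataclass(frozen=True)
class MSDCurve:
    """Time-averaged MSD of one track at lags 1..max_lag (µm²)."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    track_id: int = -1


@dataclass(frozen=True)
class DiffusionEstimate:
    """Per-track apparent diffusion coefficient from the MSD line fit."""

    track_id: int
    d: float
    r_squared: float
    accepted: bool

    @property
    def log10_d(self) -> float:
        return float(np.log10(self.d)) if self.d > 0 else float("nan")


def compute_msd(traj: Trajectory, max_lag: int = 5) -> MSDCurve:
    """Time-averaged MSD over all overlapping pairs, lags 1..max_lag."""
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if len(traj) < max_lag + 1:
        raise ValueError(
            f"track {traj.track_id} has {len(traj)} frames; need >= {max_lag + 1}"
        )
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=np.int64)
    for i, n in enumerate(lags):
        dx = traj.x[n:] - traj.x[:-n]
        dy = traj.y[n:] - traj.y[:-n]
        sq = dx**2 + dy**2
        msd[i] = sq.mean()
        n_pairs[i] = len(sq)
    return MSDCurve(lags=lags, msd=msd, n_pairs=n_pairs, track_id=traj.track_id)


def estimate_d(curve: MSDCurve, dt: float) -> DiffusionEstimate:
    """OLS of MSD on lag time over lags 2–5 (free intercept); D = slope/4."""
    present = {int(l): float(m) for l, m in zip(curve.lags, curve.msd)}
    if any(l not in present for l in FIT_LAGS):
        raise ValueError("MSD curve must contain lags 2..5")
    t = np.array(FIT_LAGS, dtype=float) * dt
    y = np.array([present[l] for l in FIT_LAGS])
    slope, intercept = np.polyfit(t, y, 1)
    ss_res = float(((y - (slope * t + intercept)) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    d = slope / 4.0
    accepted = bool(r2 > R2_THRESHOLD and slope > 0)
    return DiffusionEstimate(track_id=curve.track_id, d=float(d),
                             r_squared=float(r2), accepted=accepted)


def analyze_tracks(trajs: TrajectorySet, max_lag: int = 5,
                   min_len: int = 6) -> list[DiffusionEstimate]:
    """MSD-based D estimates for all tracks of at least ``min_len`` frames."""
    min_required = max(min_len, max_lag + 1)
    out = []
    for t in trajs:
        if len(t) < min_required:
            continue
        out.append(estimate_d(compute_msd(t, max_lag), trajs.dt))
    logger.info("MSD analysis: %d of %d tracks long enough; %d accepted (R^2 > %.2f)",
                len(out), len(trajs), sum(e.accepted for e in out), R2_THRESHOLD)
    return out


def log_d_distribution(estimates: list[DiffusionEstimate]) -> np.ndarray:
    """log10 D of accepted tracks; warns below the n > 1000 working regime."""
    if not estimates:
        raise ValueError("no diffusion estimates supplied")
    vals = np.array([e.log10_d for e in estimates if e.accepted])
    n_rej = len(estimates) - len(vals)
    logger.info("log D distribution: %d accepted, %d rejected tracks", len(vals), n_rej)
    if len(vals) == 0:
        raise ValueError("all tracks rejected by the R^2/positive-slope filter")
    if len(vals) <= 1000:
        warnings.warn(
            f"only {len(vals)} accepted tracks; population fractions are "
            "typically estimated from > 1000 trajectories", stacklevel=2)
    return vals


@dataclass
class MixtureFit:
    """Two-component Gaussian fit of the log10 D distribution.

    Components are ordered slow then fast by mean; the slow weight is the
    mixture-based chromatin-bound fraction. SE fields are populated by
    :func:`bootstrap_mixture`.
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    converged: bool
    n: int
    se_weights: tuple[float, float] | None = None
    se_means: tuple[float, float] | None = None
    se_sds: tuple[float, float] | None = None
    n_boot: int = 0

    @property
    def f_bound(self) -> float:
        return self.weights[0]

    def summary(self) -> dict:
        out = {
            "f_bound_msd": self.weights[0],
            "weights": list(self.weights),
            "means_log10d": list(self.means),
            "sds_log10d": list(self.sds),
            "converged": self.converged,
            "n_tracks": self.n,
            "n_boot": self.n_boot,
        }
        if self.se_weights is not None:
            out["se_weights"] = list(self.se_weights)
            out["se_means"] = list(self.se_means)
            out["se_sds"] = list(self.se_sds)
        return out


def _fit_gmm(values: np.ndarray, seed, n_init: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    gm = GaussianMixture(n_components=2, n_init=n_init, random_state=seed,
                         covariance_type="full", max_iter=500, tol=1e-6,
                         reg_covar=1e-10)
    gm.fit(values.reshape(-1, 1))
    w = gm.weights_
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(mu)  # slow (bound) component first
    return w[order], mu[order], sd[order], bool(gm.converged_)


def fit_mixture(log10_ds: np.ndarray, n_components: int = 2, *,
                seed: int | None = None, n_init: int = 10) -> MixtureFit:
    """Maximum-likelihood two-Gaussian decomposition of log10 D values.

    EM with ``n_init`` seeded restarts; the best-likelihood solution wins.
    """
    if n_components != 2:
        raise ValueError("only the two-component model is supported")
    values = np.asarray(log10_ds, dtype=float)
    if len(values) < 50:
        raise ValueError(f"need >= 50 values to fit a mixture, got {len(values)}")
    if not np.all(np.isfinite(values)):
        raise ValueError("log10 D values must be finite")
    if np.std(values) < 1e-9:
        raise ValueError("degenerate distribution: all values (nearly) equal")
    w, mu, sd, conv = _fit_gmm(values, seed, n_init)
    if not conv:
        logger.warning("mixture EM did not converge in any restart")
    return MixtureFit(weights=(float(w[0]), float(w[1])),
                      means=(float(mu[0]), float(mu[1])),
                      sds=(float(sd[0]), float(sd[1])),
                      converged=conv, n=len(values))


def bootstrap_mixture(log10_ds: np.ndarray, n_boot: int = 100, *,
                      seed: int | None = None, n_init: int = 10,
                      n_init_boot: int = 3) -> MixtureFit:
    """Mixture fit with bootstrap standard errors.

    Resamples the trajectory-level log10 D values with replacement, refits
    each replicate, and reports the across-replicate SD of every parameter
    as its standard error. Label switching is resolved by ordering the
    components by mean before aggregating.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2 (>= 100 recommended)")
    values = np.asarray(log10_ds, dtype=float)
    fit = fit_mixture(values, seed=seed, n_init=n_init)
    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, 6))
    for b in range(n_boot):
        sample = values[rng.integers(0, len(values), size=len(values))]
        try:
            w, mu, sd, _ = _fit_gmm(sample, int(rng.integers(0, 2**31 - 1)), n_init_boot)
        except ValueError:
            reps[b] = np.nan
            continue
        reps[b] = np.concatenate([w, mu, sd])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se = np.nanstd(reps, axis=0, ddof=1)
    fit.se_weights = (float(se[0]), float(se[1]))
    fit.se_means = (float(se[2]), float(se[3]))
    fit.se_sds = (float(se[4]), float(se[5]))
    fit.n_boot = n_boot
    return fit
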