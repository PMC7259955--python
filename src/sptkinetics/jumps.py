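"""Two-state kinetic modeling of jump-length distributions.

The displacement ("jump length") r of a 2D Brownian particle over a time
interval Δτ is Rayleigh distributed,

    P(r, Δτ) = r / (2DΔτ) · exp(−r² / (4DΔτ)),

with CDF 1 − exp(−r²/(4DΔτ)). Localization error σ per axis inflates the
apparent variance, DΔτ → DΔτ + σ². A population with a chromatin-bound
fraction F₁ (diffusing at D₁) and a free fraction F₂ = 1 − F₁ (at D₂) gives
the two-state mixture

    p(r, Δτ) = F₁·P(r; D₁Δτ+σ²) + Z(Δτ, Δz, D₂)·F₂·P(r; D₂Δτ+σ²),

where Z ≤ 1 corrects for fast molecules diffusing axially out of the finite
detection slab of thickness Δz before the end of the interval. Fitting the
model CDF jointly across several interval multiples k·dt recovers F₁, D₁,
D₂ and σ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from .tracks import TrajectorySet

__all__ = [
    "JumpSettings",
    "JumpData",
    "compile_jumps",
    "single_state_pdf",
    "single_state_cdf",
    "z_correction",
    "TwoStateModelParams",
    "ParamBounds",
    "DEFAULT_BOUNDS",
    "two_state_pdf",
    "two_state_cdf",
    "TwoStateFit",
    "fit_two_state",
    "bootstrap_two_state",
]


# ---------------------------------------------------------------------------
# jump compilation

@dataclass(frozen=True)
class JumpSettings:
    """How displacements are compiled into per-interval distributions.

    Defaults follow standard kinetic-modeling practice for 10 ms frame
    intervals: 6 interval multiples, at most 4 jumps per trajectory per
    interval, jumps beyond 1.2 µm discarded, 0.01 µm CDF bin width.
    """

    n_timepoints: int = 6
    jumps_per_track: int = 4
    max_jump: float = 1.2
    bin_width: float = 0.01
    min_track_len: int = 3

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.jumps_per_track < 1:
            raise ValueError("jumps_per_track must be >= 1")
        if self.max_jump <= 0 or self.bin_width <= 0:
            raise ValueError("max_jump and bin_width must be positive")
        if self.min_track_len < 3:
            raise ValueError("min_track_len must be >= 3")

    @property
    def bin_edges(self) -> np.ndarray:
        n_bins = int(round(self.max_jump / self.bin_width))
        return np.linspace(0.0, n_bins * self.bin_width, n_bins + 1)


@dataclass
class JumpData:
    """Displacements grouped by interval multiple k (Δτ = k·dt).

    ``track_lengths`` records the lengths of the eligible trajectories; the
    fit uses them to estimate the photobleaching survival per frame, which
    enters the observation-process (track-composition) weighting.
    """

    jumps: dict[int, np.ndarray]
    dt: float
    settings: JumpSettings
    track_lengths: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def n_jumps(self) -> int:
        return sum(len(v) for v in self.jumps.values())

    def empirical_cdf(self, k: int) -> np.ndarray:
        """Empirical CDF of the lag-k jumps evaluated at the bin edges."""
        r = self.jumps[k]
        if len(r) == 0:
            raise ValueError(f"no jumps at interval multiple {k}")
        edges = self.settings.bin_edges
        return np.searchsorted(np.sort(r), edges, side="right") / len(r)


def compile_jumps(trajs: TrajectorySet, settings: JumpSettings | None = None) -> JumpData:
    """Collect per-interval jump lengths from a set of trajectories.

    For each interval multiple k, each trajectory of >= ``min_track_len``
    frames contributes its earliest ``jumps_per_track`` displacements between
    positions k frames apart; displacements longer than ``max_jump`` are
    discarded.
    """
    settings = settings or JumpSettings()
    jumps: dict[int, list[np.ndarray]] = {k: [] for k in range(1, settings.n_timepoints + 1)}
    lengths = []
    for t in trajs:
        if len(t) < settings.min_track_len:
            continue
        lengths.append(len(t))
        for k in range(1, settings.n_timepoints + 1):
            r = t.displacements(k)[: settings.jumps_per_track]
            if len(r):
                jumps[k].append(r[r <= settings.max_jump])
    if not lengths:
        raise ValueError(
            f"no eligible trajectories (need >= {settings.min_track_len} frames)"
        )
    out = {
        k: (np.concatenate(v) if v else np.empty(0)) for k, v in jumps.items()
    }
    return JumpData(jumps=out, dt=trajs.dt, settings=settings,
                    track_lengths=np.asarray(lengths, dtype=np.int64))


# ---------------------------------------------------------------------------
# single-state displacement law

def single_state_pdf(r, d: float, delta_tau: float):
    """Rayleigh jump-length density for one diffusive state (no noise term)."""
    if d <= 0:
        raise ValueError("d must be positive")
    if delta_tau <= 0:
        raise ValueError("delta_tau must be positive")
    r = np.asarray(r, dtype=float)
    s = 2.0 * d * delta_tau
    return r / s * np.exp(-(r**2) / (2.0 * s))


def single_state_cdf(r, d: float, delta_tau: float):
    """CDF of the single-state law: 1 − exp(−r²/(4DΔτ))."""
    if d <= 0:
        raise ValueError("d must be positive")
    if delta_tau <= 0:
        raise ValueError("delta_tau must be positive")
    r = np.asarray(r, dtype=float)
    return 1.0 - np.exp(-(r**2) / (4.0 * d * delta_tau))


# ---------------------------------------------------------------------------
# axial (defocalization) correction

def z_correction(delta_tau: float, dz: float, d_free: float) -> float:
    """Fraction of molecules still inside an absorbing slab after ``delta_tau``.

    Solves 1D diffusion between absorbing planes a distance ``dz`` apart with
    a uniform initial distribution. For a = π²·D·Δτ/dz² >= 0.01 the
    eigenfunction series

        S = (8/π²) Σ_{n odd} n⁻² exp(−n²·a)

    is summed until terms fall below 1e−12. For smaller a (where the series
    converges slowly) the short-time boundary-layer expansion
    S = 1 − (4/√π)·√(DΔτ)/dz is used; at the crossover the two expressions
    agree to ~1e−12 (wall-interaction terms are O(exp(−dz²/4DΔτ))).
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    if delta_tau <= 0:
        raise ValueError("delta_tau must be positive")
    if d_free < 0:
        raise ValueError("d_free must be non-negative")
    if d_free == 0.0:
        return 1.0
    a = math.pi**2 * d_free * delta_tau / dz**2
    if a < 0.01:
        return 1.0 - (4.0 / math.sqrt(math.pi)) * math.sqrt(d_free * delta_tau) / dz
    total = 0.0
    n = 1
    pref = 8.0 / math.pi**2
    while True:
        term = pref * math.exp(-(n**2) * a) / n**2
        total += term
        if term < 1e-12:
            break
        n += 2
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# two-state model

@dataclass(frozen=True)
class TwoStateModelParams:
    """Parameters of the two-state jump-length model."""

    f_bound: float
    d_bound: float
    d_free: float
    sigma: float
    dz: float = 0.65

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_bound <= 1.0:
            raise ValueError("f_bound must be in [0, 1]")
        if self.d_bound < 0 or self.d_free < 0:
            raise ValueError("diffusion coefficients must be non-negative")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.dz <= 0:
            raise ValueError("dz must be positive")


@dataclass(frozen=True)
class ParamBounds:
    """Box bounds for the fit (standard kinetic-modeling defaults)."""

    d_bound: tuple[float, float] = (0.001, 0.1)
    d_free: tuple[float, float] = (0.15, 5.0)
    f_bound: tuple[float, float] = (0.0, 1.0)
    sigma: tuple[float, float] = (0.01, 0.1)


DEFAULT_BOUNDS = ParamBounds()


def _mixture_terms(r, delta_tau, p: TwoStateModelParams, zcorr):
    sb = p.d_bound * delta_tau + p.sigma**2
    sf = p.d_free * delta_tau + p.sigma**2
    zc = z_correction(delta_tau, p.dz, p.d_free) if zcorr is None else zcorr
    return sb, sf, zc


def two_state_pdf(r, delta_tau: float, params: TwoStateModelParams, *,
                  zcorr: float | None = None, normalize: bool = False,
                  r_max: float = 1.2):
    """Two-state jump-length density at interval Δτ.

    ``zcorr`` overrides the computed axial correction (useful for analytic
    checks). With ``normalize=True`` the density is rescaled to unit mass on
    [0, r_max]; the raw form has mass F₁ + Z·F₂ < 1.
    """
    r = np.asarray(r, dtype=float)
    sb, sf, zc = _mixture_terms(r, delta_tau, params, zcorr)
    f1, f2 = params.f_bound, 1.0 - params.f_bound
    pdf = (f1 * r / (2.0 * sb) * np.exp(-(r**2) / (4.0 * sb))
           + zc * f2 * r / (2.0 * sf) * np.exp(-(r**2) / (4.0 * sf)))
    if normalize:
        mass = (f1 * (1.0 - np.exp(-(r_max**2) / (4.0 * sb)))
                + zc * f2 * (1.0 - np.exp(-(r_max**2) / (4.0 * sf))))
        pdf = pdf / mass
    return pdf


def two_state_cdf(r, delta_tau: float, params: TwoStateModelParams, *,
                  zcorr: float | None = None, normalize: bool = False,
                  r_max: float = 1.2):
    """CDF of the two-state model (optionally normalized over [0, r_max])."""
    r = np.asarray(r, dtype=float)
    sb, sf, zc = _mixture_terms(r, delta_tau, params, zcorr)
    f1, f2 = params.f_bound, 1.0 - params.f_bound
    cdf = (f1 * (1.0 - np.exp(-(r**2) / (4.0 * sb)))
           + zc * f2 * (1.0 - np.exp(-(r**2) / (4.0 * sf))))
    if normalize:
        mass = (f1 * (1.0 - np.exp(-(r_max**2) / (4.0 * sb)))
                + zc * f2 * (1.0 - np.exp(-(r_max**2) / (4.0 * sf))))
        cdf = cdf / mass
    return cdf


# ---------------------------------------------------------------------------
# fitting

@dataclass
class TwoStateFit:
    """Result of the two-state CDF fit."""

    params: TwoStateModelParams
    objective: float
    n_iterations_used: int
    converged: bool
    n_jumps: int
    residuals: dict[int, np.ndarray] = field(default_factory=dict)
    param_se: dict[str, float] = field(default_factory=dict)

    def summary(self) -> dict:
        p = self.params
        return {
            "f_bound": p.f_bound,
            "d_bound_um2s": p.d_bound,
            "d_free_um2s": p.d_free,
            "sigma_um": p.sigma,
            "dz_um": p.dz,
            "objective": self.objective,
            "converged": self.converged,
            "n_jumps": self.n_jumps,
            "param_se": dict(self.param_se),
        }


def _composition_weight(k: int, dt: float, dz: float, d_free: float, q: float,
                        cap: int, min_len: int) -> float:
    """Expected free:bound ratio of compiled lag-k jump counts.

    A lag-k jump i -> i+k (earliest-first, at most ``cap`` per track) is
    observed iff the track lives at least max(i+k+1, min_len) frames.
    Photobleaching survival per frame is q for both states; a free molecule
    additionally has to stay inside the absorbing slab, with survival given
    by the same series solution as :func:`z_correction`. Bleaching and axial
    loss are independent, so the expected count per molecule is a sum of
    products of the two marginal survival terms, and the common bleaching
    factors cancel only partially — hence the explicit q dependence.
    """
    num = den = 0.0
    for i in range(cap):
        m = max(i + k + 1, min_len)
        w = q ** (m - 1)
        den += w
        num += w * z_correction((m - 1) * dt, dz, d_free)
    return num / den


def _mean_len_free(q: float, dt: float, dz: float, d_free: float,
                   min_len: int, max_m: int = 300) -> float:
    """E[track length | length >= min_len] for a free molecule."""
    ps = np.array([q ** (m - 1) * z_correction((m - 1) * dt, dz, d_free)
                   for m in range(min_len, max_m)])
    return (min_len - 1) + ps.sum() / ps[0]


def _estimate_q(jumps: JumpData, dz: float, f_bound: float | None = None,
                d_free: float | None = None) -> float:
    """Per-frame photobleaching survival from the track-length distribution.

    First pass: treat all eligible tracks as geometric (memoryless), giving
    q = 1 - 1/(mean - (min_len - 1)). Once a provisional fit is available,
    the free tracks' extra axial attrition is accounted for by solving for
    the q at which the bound/free length mixture reproduces the observed
    mean length.
    """
    min_len = jumps.settings.min_track_len
    mean_obs = float(jumps.track_lengths.mean())
    q0 = 1.0 - 1.0 / max(mean_obs - (min_len - 1), 1.05)
    q0 = min(max(q0, 0.05), 0.999)
    if f_bound is None or d_free is None or f_bound >= 0.999:
        return q0

    s_min = z_correction((min_len - 1) * jumps.dt, dz, d_free)

    def gap(q: float) -> float:
        share_b = f_bound / (f_bound + (1.0 - f_bound) * s_min)
        mean_b = (min_len - 1) + 1.0 / (1.0 - q)
        mean_f = _mean_len_free(q, jumps.dt, dz, d_free, min_len)
        return share_b * mean_b + (1.0 - share_b) * mean_f - mean_obs

    try:
        return float(brentq(gap, 0.3, 0.9995))
    except ValueError:
        return q0


def fit_two_state(jumps: JumpData, *, dz: float = 0.65,
                  bounds: ParamBounds = DEFAULT_BOUNDS,
                  n_iterations: int = 3, seed: int | None = None,
                  composition: str = "track") -> TwoStateFit:
    """Fit the two-state model to empirical jump-length CDFs.

    Bounded least squares on the deviation between the model CDF (normalized
    over the considered jump range) and the empirical CDF, evaluated at the
    bin edges, jointly across all interval multiples; each interval is
    weighted by the square root of its jump count. ``n_iterations`` random
    initializations are drawn within the bounds from the given seed; the
    best final objective wins. The localization error σ is fitted from the
    data; ``dz`` is fixed (it is set by the dye/optics).

    ``composition`` selects how the free component is weighted per interval:

    - ``"track"`` (default): expected jump-count composition of the finite
      observed tracks — the absorbing-slab survival evaluated over the
      frames each compiled jump actually requires the molecule to remain
      detectable (minimum track length, earliest-first jump cap,
      photobleaching estimated from the track-length distribution). This is
      the self-consistent weighting for track-limited data and is refined
      once against the provisional fit.
    - ``"instantaneous"``: the textbook form Z(Δτ)·F₂ with Z evaluated at
      the jump interval only; it ignores that a jump must come from a track
      that already survived several frames, which overestimates the bound
      fraction on track-limited data.
    """
    if composition not in ("track", "instantaneous"):
        raise ValueError("composition must be 'track' or 'instantaneous'")
    ks = [k for k, v in jumps.jumps.items() if len(v) > 0]
    if len(ks) < 2:
        raise ValueError("need jumps at >= 2 interval multiples to fit")
    st = jumps.settings
    edges = st.bin_edges
    r_max = edges[-1]
    emp = {k: jumps.empirical_cdf(k) for k in ks}
    taus = {k: k * jumps.dt for k in ks}
    n_max = max(len(jumps.jumps[k]) for k in ks)
    lag_w = {k: math.sqrt(len(jumps.jumps[k]) / n_max) for k in ks}

    lo = np.array([bounds.f_bound[0], bounds.d_bound[0], bounds.d_free[0], bounds.sigma[0]])
    hi = np.array([bounds.f_bound[1], bounds.d_bound[1], bounds.d_free[1], bounds.sigma[1]])

    def make_residual(q: float | None):
        def residual(theta: np.ndarray) -> np.ndarray:
            f1, d1, d2, sig = theta
            p = TwoStateModelParams(f_bound=f1, d_bound=d1, d_free=d2, sigma=sig, dz=dz)
            out = []
            for k in ks:
                if composition == "track":
                    zc = _composition_weight(k, jumps.dt, dz, d2, q,
                                             st.jumps_per_track, st.min_track_len)
                else:
                    zc = None  # plain Z(Δτ), computed inside two_state_cdf
                model = two_state_cdf(edges, taus[k], p, zcorr=zc,
                                      normalize=True, r_max=r_max)
                out.append(lag_w[k] * (model - emp[k]))
            return np.concatenate(out)
        return residual

    def solve(residual):
        rng = np.random.default_rng(seed)
        best = None
        n_ok = 0
        for _ in range(n_iterations):
            x0 = lo + (hi - lo) * rng.uniform(size=4)
            try:
                res = least_squares(residual, x0, bounds=(lo, hi), method="trf",
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:
                continue
            if not np.all(np.isfinite(res.fun)):
                continue
            n_ok += 1
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError(
                f"two-state fit failed to converge in any of {n_iterations} starts"
            )
        return best, n_ok

    if composition == "track":
        q = _estimate_q(jumps, dz)
        best, n_ok = solve(make_residual(q))
        for _ in range(2):  # refine q with the provisional state composition
            q = _estimate_q(jumps, dz, f_bound=float(best.x[0]), d_free=float(best.x[2]))
            best, n_ok = solve(make_residual(q))
    else:
        best, n_ok = solve(make_residual(None))

    f1, d1, d2, sig = best.x
    params = TwoStateModelParams(f_bound=float(f1), d_bound=float(d1),
                                 d_free=float(d2), sigma=float(sig), dz=dz)
    residual = make_residual(q if composition == "track" else None)
    resid = residual(best.x)
    per_k = {}
    m = len(edges)
    for i, k in enumerate(ks):
        per_k[k] = resid[i * m:(i + 1) * m]

    # residual-covariance standard errors (Gauss-Newton approximation)
    se: dict[str, float] = {}
    try:
        jac = best.jac
        dof = max(len(resid) - 4, 1)
        s2 = 2.0 * best.cost / dof
        cov = s2 * np.linalg.pinv(jac.T @ jac)
        for name, var in zip(["f_bound", "d_bound", "d_free", "sigma"], np.diag(cov)):
            se[name] = float(math.sqrt(max(var, 0.0)))
    except np.linalg.LinAlgError:
        pass

    return TwoStateFit(
        params=params,
        objective=float(2.0 * best.cost),  # sum of squared residuals
        n_iterations_used=n_ok,
        converged=bool(best.success),
        n_jumps=jumps.n_jumps(),
        residuals=per_k,
        param_se=se,
    )


def bootstrap_two_state(trajs: TrajectorySet, *,
                        settings: JumpSettings | None = None,
                        dz: float = 0.65, n_boot: int = 50,
                        n_iterations: int = 3,
                        seed: int | None = None) -> TwoStateFit:
    """Two-state fit with bootstrap standard errors over trajectories.

    Whole trajectories (the independent sampling unit) are resampled with
    replacement, jumps recompiled and the model refitted per replicate; the
    across-replicate SD of each parameter is stored in ``param_se`` under
    ``<name>_boot`` keys, alongside the residual-covariance SEs of the point
    fit. The latter treat CDF residuals as independent and are typically
    optimistic; the bootstrap values are the ones to quote.
    """
    from .tracks import Trajectory

    settings = settings or JumpSettings()
    point = fit_two_state(compile_jumps(trajs, settings), dz=dz,
                          n_iterations=n_iterations, seed=seed)
    rng = np.random.default_rng(seed)
    pool = trajs.trajectories
    reps = np.empty((n_boot, 4))
    for b in range(n_boot):
        idx = rng.integers(0, len(pool), size=len(pool))
        resampled = [
            Trajectory(track_id=j, frames=pool[i].frames, x=pool[i].x, y=pool[i].y)
            for j, i in enumerate(idx)
        ]
        boot_set = TrajectorySet(trajectories=resampled, dt=trajs.dt)
        try:
            fit_b = fit_two_state(compile_jumps(boot_set, settings), dz=dz,
                                  n_iterations=n_iterations,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        except (ValueError, RuntimeError):
            reps[b] = np.nan
            continue
        p = fit_b.params
        reps[b] = (p.f_bound, p.d_bound, p.d_free, p.sigma)
    se = np.nanstd(reps, axis=0, ddof=1)
    for name, val in zip(["f_bound", "d_bound", "d_free", "sigma"], se):
        point.param_se[f"{name}_boot"] = float(val)
    return point
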