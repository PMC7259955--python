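"""Jump compilation, displacement laws, axial correction, two-state fit."""

import numpy as np
import pytest
from scipy import integrate

from sptkinetics import (
    JumpSettings,
    SimConfig,
    TwoStateModelParams,
    compile_jumps,
    fit_two_state,
    simulate_trajectories,
    single_state_cdf,
    single_state_pdf,
    two_state_cdf,
    two_state_pdf,
    z_correction,
)
from sptkinetics.linking import filter_min_length
from sptkinetics.tracks import Trajectory, TrajectorySet


def track_of_length(n, tid=0, step=0.05):
    return Trajectory(track_id=tid, frames=np.arange(n),
                      x=step * np.arange(n), y=np.zeros(n))


def as_set(*tracks, dt=0.01):
    return TrajectorySet(trajectories=list(tracks), dt=dt)


class TestCompileJumps:
    def test_three_frame_track_jump_counts(self):
        data = compile_jumps(as_set(track_of_length(3)))
        assert len(data.jumps[1]) == 2
        assert len(data.jumps[2]) == 1
        for k in range(3, 7):
            assert len(data.jumps[k]) == 0

    def test_long_track_capped_at_four_jumps_per_interval(self):
        data = compile_jumps(as_set(track_of_length(20)))
        for k in range(1, 7):
            assert len(data.jumps[k]) == 4

    def test_jumps_beyond_max_excluded(self):
        t = Trajectory(track_id=0, frames=np.arange(3),
                       x=np.array([0.0, 1.3, 1.35]), y=np.zeros(3))
        data = compile_jumps(as_set(t))
        assert len(data.jumps[1]) == 1  # the 1.3 µm jump is dropped
        assert np.all(data.jumps[1] <= 1.2)

    def test_short_tracks_ineligible(self):
        with pytest.raises(ValueError, match="eligible"):
            compile_jumps(as_set(track_of_length(2)))

    def test_empirical_cdf_monotone_zero_to_one(self):
        cfg = SimConfig(n_molecules=300, f_bound=0.5, d_bound=0.02, d_free=1.0,
                        seed=3)
        data = compile_jumps(filter_min_length(simulate_trajectories(cfg), 3))
        for k in (1, 3, 6):
            cdf = data.empirical_cdf(k)
            assert cdf[0] >= 0.0 and cdf[-1] == pytest.approx(1.0)
            assert np.all(np.diff(cdf) >= 0)


class TestSingleStateLaw:
    def test_density_zero_at_origin(self):
        assert single_state_pdf(0.0, 1.0, 0.01) == 0.0

    def test_cdf_analytic_identity_at_characteristic_radius(self):
        d, tau = 0.7, 0.02
        r = np.sqrt(4 * d * tau)
        assert single_state_cdf(r, d, tau) == pytest.approx(1 - np.exp(-1), abs=1e-12)

    @pytest.mark.parametrize("d,tau", [(0.03, 0.01), (1.18, 0.06), (5.0, 0.01)])
    def test_density_integrates_to_one(self, d, tau):
        val, _ = integrate.quad(lambda r: single_state_pdf(r, d, tau), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            single_state_pdf(0.1, 0.0, 0.01)
        with pytest.raises(ValueError):
            single_state_cdf(0.1, 1.0, -0.01)


class TestZCorrection:
    def test_immobile_population_fully_retained(self):
        assert z_correction(0.06, 0.65, 0.0) == 1.0

    def test_wide_slab_limit_approaches_one(self):
        assert z_correction(0.01, 1e4, 1.0) == pytest.approx(1.0, abs=1e-4)

    def test_monotone_in_diffusion_time_and_slab(self):
        ds = [0.15, 0.5, 1.18, 5.0]
        surv = [z_correction(0.02, 0.6, d) for d in ds]
        assert np.all(np.diff(surv) < 0)
        taus = [0.01, 0.02, 0.04, 0.06]
        surv = [z_correction(t, 0.6, 1.0) for t in taus]
        assert np.all(np.diff(surv) < 0)
        assert z_correction(0.02, 0.65, 1.0) > z_correction(0.02, 0.6, 1.0)

    @pytest.mark.parametrize("a", [1e-5, 0.002, 0.009, 0.02, 0.1, 1.0])
    def test_matches_reference_eigenseries_across_both_branches(self, a):
        """Oracle: densely truncated eigensum S=(8/π²)Σ n⁻² exp(−n²a)."""
        dz, tau = 0.65, 0.01
        d = a * dz**2 / (np.pi**2 * tau)
        ref, n = 0.0, 1
        while True:
            term = 8 / np.pi**2 * np.exp(-(n**2) * a) / n**2
            ref += term
            if term < 1e-17:
                break
            n += 2
        assert z_correction(tau, dz, d) == pytest.approx(min(ref, 1.0), abs=1e-9)

    def test_matches_monte_carlo_absorbing_slab(self):
        """Independent MC oracle: frame steps + Brownian-bridge absorption."""
        from conftest import mc_slab_survival
        rng = np.random.default_rng(77)
        dz, d, dt, k = 0.6, 1.18, 0.01, 4
        surv = mc_slab_survival(rng, 100_000, dz, d, dt, k)
        assert surv[-1] == pytest.approx(z_correction(k * dt, dz, d), abs=0.005)


class TestTwoStateModel:
    def test_all_bound_reduces_to_single_state_with_noise_scale(self):
        p = TwoStateModelParams(f_bound=1.0, d_bound=0.05, d_free=1.0,
                                sigma=0.03, dz=0.65)
        r = np.linspace(0, 0.5, 80)
        tau = 0.01
        d_eff = 0.05 + 0.03**2 / tau
        assert two_state_pdf(r, tau, p) == pytest.approx(
            single_state_pdf(r, d_eff, tau))

    def test_equal_ds_collapse_to_single_state(self):
        p = TwoStateModelParams(f_bound=0.5, d_bound=0.8, d_free=0.8,
                                sigma=0.0, dz=0.65)
        r = np.linspace(0.01, 0.6, 50)
        assert two_state_pdf(r, 0.01, p, zcorr=1.0) == pytest.approx(
            single_state_pdf(r, 0.8, 0.01))

    def test_cdf_monotone_and_weights_sum_before_correction(self):
        p = TwoStateModelParams(f_bound=0.6, d_bound=0.03, d_free=1.2,
                                sigma=0.03, dz=0.65)
        r = np.linspace(0, 1.2, 200)
        cdf = two_state_cdf(r, 0.02, p, zcorr=1.0)
        assert np.all(np.diff(cdf) >= 0)
        # with zcorr forced to 1, total mass -> F1 + F2 = 1 as r -> inf
        assert two_state_cdf(50.0, 0.02, p, zcorr=1.0) == pytest.approx(1.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TwoStateModelParams(f_bound=1.2, d_bound=0.03, d_free=1.0,
                                sigma=0.03)


class TestTwoStateFit:
    @staticmethod
    def jump_data(f_bound, n=4000, seed=0, d_free=1.0, dz=0.6):
        cfg = SimConfig(n_molecules=n, f_bound=f_bound, d_bound=0.01,
                        d_free=d_free, sigma_loc=0.03, dz=dz, seed=seed)
        return compile_jumps(filter_min_length(simulate_trajectories(cfg), 3))

    def test_recovers_generative_parameters(self):
        """Half-bound population: F within ±0.03, D_free within ±10%."""
        data = self.jump_data(0.5, n=12000, seed=41)
        fit = fit_two_state(data, dz=0.6, seed=42)
        assert data.n_jumps() >= 30_000
        assert fit.params.f_bound == pytest.approx(0.5, abs=0.03)
        assert fit.params.d_free == pytest.approx(1.0, rel=0.10)

    def test_all_bound_population_fits_near_one(self):
        data = self.jump_data(1.0, n=2500, seed=43)
        fit = fit_two_state(data, dz=0.6, seed=44)
        assert fit.params.f_bound >= 0.97

    def test_same_seed_identical_fit(self):
        data = self.jump_data(0.5, n=1500, seed=45)
        a = fit_two_state(data, dz=0.6, seed=46)
        b = fit_two_state(data, dz=0.6, seed=46)
        assert a.params == b.params
        assert a.objective == b.objective

    def test_model_cdf_matches_empirical_at_generative_params(self):
        """Generative consistency of the fitted model under the
        track-composition weighting actually used by the fit."""
        from sptkinetics.jumps import _composition_weight, _estimate_q
        data = self.jump_data(0.5, n=12000, seed=47)
        fit = fit_two_state(data, dz=0.6, seed=48)
        st = data.settings
        edges = st.bin_edges
        q = _estimate_q(data, 0.6, f_bound=fit.params.f_bound,
                        d_free=fit.params.d_free)
        for k in (1, 3, 6):
            emp = data.empirical_cdf(k)
            zc = _composition_weight(k, data.dt, 0.6, fit.params.d_free, q,
                                     st.jumps_per_track, st.min_track_len)
            model = np.asarray(two_state_cdf(edges, k * data.dt, fit.params,
                                             zcorr=zc, normalize=True))
            assert np.abs(model - emp).max() < 0.02

    def test_needs_at_least_two_intervals(self):
        # the only 2-frame-lag displacement exceeds max_jump, leaving one interval
        t = Trajectory(track_id=0, frames=np.arange(3),
                       x=np.array([0.0, 0.7, 1.4]), y=np.zeros(3))
        data = compile_jumps(as_set(t))
        with pytest.raises(ValueError, match=">= 2 interval"):
            fit_two_state(data, seed=1)

    def test_residual_standard_errors_reported(self):
        data = self.jump_data(0.5, n=1500, seed=49)
        fit = fit_two_state(data, dz=0.6, seed=50)
        assert set(fit.param_se) == {"f_bound", "d_bound", "d_free", "sigma"}
        assert all(v >= 0 for v in fit.param_se.values())

    def test_trajectory_bootstrap_errors_exceed_residual_errors(self):
        """Resampling whole tracks captures the real sampling unit; the
        residual-covariance SEs treat correlated CDF points as independent
        and come out smaller."""
        from sptkinetics import bootstrap_two_state
        cfg = SimConfig(n_molecules=1200, f_bound=0.5, d_bound=0.01,
                        d_free=1.0, sigma_loc=0.03, dz=0.6, seed=51)
        trajs = filter_min_length(simulate_trajectories(cfg), 3)
        fit = bootstrap_two_state(trajs, dz=0.6, n_boot=10, seed=52)
        assert "f_bound_boot" in fit.param_se
        assert fit.param_se["f_bound_boot"] > fit.param_se["f_bound"]
        assert 0.001 < fit.param_se["f_bound_boot"] < 0.2
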