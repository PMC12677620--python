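"""MSD estimation, GSER inversion, viscosity spectrum, Maxwell fitting."""
import warnings

import numpy as np
import pandas as pd
import pytest

from pcmrheo import (
    MediumModel,
    ModuliCurves,
    MSDCurve,
    SimConfig,
    TrajectorySet,
    analytic_moduli,
    analytic_msd,
    simulate_trajectories,
)
from pcmrheo.rheology import (
    crossover_time,
    default_lag_grid,
    ensemble_msd,
    fit_maxwell,
    gser_moduli,
    second_crossover,
    smooth_msd,
    viscosity_spectrum,
    zero_shear_viscosity,
)


class TestEnsembleMSD:
    def test_default_grid_endpoints(self):
        grid = default_lag_grid()
        assert grid[0] == pytest.approx(0.015)
        assert grid[-1] == pytest.approx(100.0)

    def test_two_point_trajectory_definition(self):
        data = pd.DataFrame(
            {
                "trajectory_id": [0, 0],
                "frame": [0, 1],
                "t_s": [0.0, 0.015],
                "x_um": [0.0, 0.3],
                "y_um": [0.0, -0.4],
            }
        )
        traj = TrajectorySet(data=data, dt=0.015)
        curve = ensemble_msd(traj, lag_grid=np.array([0.015]))
        assert curve.msd[0] == pytest.approx(0.3**2 + 0.4**2)
        assert curve.n_obs[0] == 1

    def test_overlong_lags_dropped_with_warning(self):
        data = pd.DataFrame(
            {
                "trajectory_id": [0, 0, 0],
                "frame": [0, 1, 2],
                "t_s": [0.0, 0.015, 0.03],
                "x_um": [0.0, 0.1, 0.2],
                "y_um": [0.0, 0.0, 0.0],
            }
        )
        traj = TrajectorySet(data=data, dt=0.015)
        with pytest.warns(UserWarning, match="dropped"):
            curve = ensemble_msd(traj, lag_grid=np.array([0.015, 1.5]))
        assert curve.lags.size == 1


class TestSmoothMSD:
    @staticmethod
    def _noisy_curve(seed=0):
        m = MediumModel.maxwell(2.0, 0.5)
        grid = default_lag_grid(0.015, 10.0)
        oracle = analytic_msd(m, grid)
        rng = np.random.default_rng(seed)
        noisy = oracle.msd * (1.0 + 0.05 * rng.normal(size=oracle.msd.size))
        return oracle, MSDCurve(lags=grid, msd=np.abs(noisy), n_obs=oracle.n_obs)

    def test_tiny_span_is_identity_with_warning(self):
        oracle, noisy = self._noisy_curve()
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = smooth_msd(noisy, span_fraction=0.001)
        assert np.array_equal(out.msd, noisy.msd)

    def test_monotone_input_stays_monotone(self):
        m = MediumModel.maxwell(2.0, 0.5)
        curve = analytic_msd(m, default_lag_grid(0.015, 10.0))
        out = smooth_msd(curve, span_fraction=0.08)
        assert np.all(np.diff(out.msd) > 0)

    def test_smoothing_reduces_error_against_oracle(self):
        oracle, noisy = self._noisy_curve(seed=3)
        out = smooth_msd(noisy, span_fraction=0.08)
        rmse_raw = np.sqrt(np.mean((noisy.msd / oracle.msd - 1.0) ** 2))
        rmse_sm = np.sqrt(np.mean((out.msd / oracle.msd - 1.0) ** 2))
        assert rmse_sm < rmse_raw

    def test_span_fraction_bounds(self):
        _, noisy = self._noisy_curve()
        with pytest.raises(ValueError):
            smooth_msd(noisy, span_fraction=0.2)


class TestGSER:
    def test_newtonian_limit(self):
        # α = 1 everywhere, G'' = ηω, G' ≈ 0
        eta = 1.0
        curve = analytic_msd(MediumModel.newtonian(eta), default_lag_grid(0.01, 100.0))
        moduli = gser_moduli(curve)
        assert np.allclose(moduli.alpha, 1.0)
        central = (moduli.omega > 0.05) & (moduli.omega < 50.0)
        assert np.allclose(moduli.Gpp[central], eta * moduli.omega[central], rtol=0.03)
        assert np.all(moduli.Gp[central] < 0.01 * moduli.Gpp[central])

    def test_maxwell_crossover_moduli(self, ca_medium):
        # at ω_c both moduli equal G0/2 = 3.46 Pa
        curve = analytic_msd(ca_medium, default_lag_grid())
        moduli = gser_moduli(curve)
        wc = 1.0 / ca_medium.tau
        i = int(np.argmin(np.abs(moduli.omega - wc)))
        assert moduli.Gp[i] == pytest.approx(ca_medium.G0 / 2.0, rel=0.15)
        assert moduli.Gpp[i] == pytest.approx(ca_medium.G0 / 2.0, rel=0.15)

    def test_plateau_msd_elastic_limit(self):
        from pcmrheo.media import K_B

        msd = MSDCurve(
            lags=np.geomspace(0.1, 10.0, 20),
            msd=np.full(20, 1e-3),
            n_obs=np.full(20, 100),
        )
        moduli = gser_moduli(msd)
        assert np.allclose(moduli.alpha, 0.0)
        expected = K_B * msd.temperature_K / (np.pi * msd.bead_radius_m * 1.5e-3 * 1e-12)
        assert np.allclose(moduli.Gp, expected, rtol=1e-9)
        assert np.allclose(moduli.Gpp, 0.0)

    def test_moduli_scale_with_temperature_and_radius(self):
        curve = analytic_msd(MediumModel.maxwell(2.0, 0.5), default_lag_grid(0.015, 10.0))
        base = gser_moduli(curve)
        hot = gser_moduli(curve, T=2 * curve.temperature_K)
        big = gser_moduli(curve, a=2 * curve.bead_radius_m)
        assert np.allclose(hot.Gpp, 2 * base.Gpp)
        assert np.allclose(big.Gpp, base.Gpp / 2)

    def test_nonpositive_msd_rejected(self):
        msd = MSDCurve(lags=np.array([0.1, 1.0]), msd=np.array([0.0, 1.0]), n_obs=np.array([1, 1]))
        with pytest.raises(ValueError):
            gser_moduli(msd)

    @pytest.mark.parametrize(
        "medium",
        [MediumModel.maxwell(31.8, 4.6), MediumModel.maxwell(3.8, 1.03), MediumModel.newtonian(0.5)],
        ids=["maxwell-CA", "maxwell-KD", "newtonian"],
    )
    def test_oracle_round_trip_within_ten_percent(self, medium):
        # gser_moduli(analytic_msd) vs closed form: complex modulus
        # within 10% over 0.1–10·ω_c (Maxwell) / the central band
        curve = analytic_msd(medium, default_lag_grid())
        est = gser_moduli(curve)
        ref = analytic_moduli(medium, est.omega)
        if medium.kind == "maxwell":
            wc = 1.0 / medium.tau
            band = (est.omega >= 0.1 * wc) & (est.omega <= 10.0 * wc)
        else:
            band = (est.omega >= 0.05) & (est.omega <= 50.0)
        err = np.abs((est.Gp + 1j * est.Gpp) - (ref.Gp + 1j * ref.Gpp))
        assert np.all(err[band] / np.abs(ref.Gp[band] + 1j * ref.Gpp[band]) < 0.10)


class TestViscositySpectrum:
    def test_newtonian_constant(self):
        moduli = analytic_moduli(MediumModel.newtonian(2.5), np.geomspace(0.1, 100, 40))
        spec = viscosity_spectrum(moduli)
        assert np.allclose(spec.eta, 2.5)

    def test_maxwell_closed_form_decreasing(self, ca_medium):
        moduli = analytic_moduli(ca_medium, np.geomspace(0.01, 10, 50))
        spec = viscosity_spectrum(moduli)
        expected = ca_medium.G0 * ca_medium.tau / (1.0 + (spec.omega * ca_medium.tau) ** 2)
        assert np.allclose(spec.eta, expected)
        assert np.all(np.diff(spec.eta) < 0)

    def test_eta_at_crossover_is_half_eta0(self, ca_medium):
        moduli = analytic_moduli(ca_medium, np.array([1.0 / ca_medium.tau]))
        spec = viscosity_spectrum(moduli)
        assert spec.eta[0] == pytest.approx(ca_medium.eta0 / 2.0)


class TestZeroShearViscosity:
    def test_maxwell_oracle_within_two_percent(self, ca_medium):
        omega = np.geomspace(0.01 / ca_medium.tau, 67.0, 80)
        spec = viscosity_spectrum(analytic_moduli(ca_medium, omega))
        out = zero_shear_viscosity(spec)
        assert out.eta0 == pytest.approx(ca_medium.eta0, rel=0.02)
        assert not out.eta0_from_fit
        assert out.plateau_range[0] >= omega[0]

    def test_newtonian_all_points_in_plateau(self):
        spec = viscosity_spectrum(
            analytic_moduli(MediumModel.newtonian(3.3), np.geomspace(0.1, 10, 30))
        )
        out = zero_shear_viscosity(spec)
        assert out.eta0 == pytest.approx(3.3, rel=1e-12)
        assert out.plateau_range == (pytest.approx(0.1), pytest.approx(10.0))

    def test_no_plateau_falls_back_to_fit(self, ca_medium):
        # sample only around ω_c where η falls steeply
        omega = np.geomspace(0.5 / ca_medium.tau, 20.0 / ca_medium.tau, 40)
        moduli = analytic_moduli(ca_medium, omega)
        spec = viscosity_spectrum(moduli)
        fit = fit_maxwell(moduli)
        out = zero_shear_viscosity(spec, fit=fit)
        assert out.eta0_from_fit
        assert out.eta0 == pytest.approx(ca_medium.eta0, rel=1e-3)
        with pytest.raises(ValueError):
            zero_shear_viscosity(viscosity_spectrum(moduli))


class TestCrossover:
    def test_maxwell_oracle_exact(self, ca_medium):
        moduli = analytic_moduli(ca_medium, np.geomspace(0.01, 10, 60))
        omega_c, tau_rel, extrapolated = crossover_time(moduli)
        assert tau_rel == pytest.approx(ca_medium.tau, rel=0.01)
        assert not extrapolated

    def test_newtonian_has_no_crossover(self):
        moduli = analytic_moduli(MediumModel.newtonian(1.0), np.geomspace(0.1, 10, 30))
        with pytest.raises(ValueError, match="no crossover"):
            crossover_time(moduli)

    def test_out_of_band_crossover_uses_fit(self, ca_medium):
        # sampled only above ω_c: measured band holds no crossing
        omega = np.geomspace(2.0 / ca_medium.tau, 100.0 / ca_medium.tau, 30)
        moduli = analytic_moduli(ca_medium, omega)
        fit = fit_maxwell(moduli)
        omega_c, tau_rel, extrapolated = crossover_time(moduli, fit=fit)
        assert extrapolated
        assert tau_rel == pytest.approx(ca_medium.tau, rel=1e-3)

    def test_single_crossover_for_maxwell(self, ca_medium):
        moduli = analytic_moduli(ca_medium, np.geomspace(0.01, 10, 60))
        assert second_crossover(moduli) is None


class TestFitMaxwell:
    def test_oracle_exact_recovery(self, kd_medium):
        moduli = analytic_moduli(kd_medium, np.geomspace(0.01, 67, 60))
        fit = fit_maxwell(moduli)
        assert fit.G0 == pytest.approx(kd_medium.G0, rel=1e-6)
        assert fit.tau == pytest.approx(kd_medium.tau, rel=1e-6)
        assert fit.eta0_fit == fit.G0 * fit.tau
        assert fit.omega_c * fit.tau == pytest.approx(1.0)
        assert fit.ok

    def test_noisy_median_recovery_within_five_percent(self, ca_medium):
        base = analytic_moduli(ca_medium, np.geomspace(0.01, 67, 60))
        rng = np.random.default_rng(1)
        g0s, taus = [], []
        for _ in range(50):
            gp = base.Gp * (1.0 + 0.05 * rng.normal(size=base.Gp.size))
            gpp = base.Gpp * (1.0 + 0.05 * rng.normal(size=base.Gpp.size))
            fit = fit_maxwell(
                ModuliCurves(omega=base.omega, Gp=np.abs(gp), Gpp=np.abs(gpp), alpha=base.alpha)
            )
            g0s.append(fit.G0)
            taus.append(fit.tau)
        assert np.median(g0s) == pytest.approx(ca_medium.G0, rel=0.05)
        assert np.median(taus) == pytest.approx(ca_medium.tau, rel=0.05)

    def test_newtonian_input_detectably_mismatched(self):
        moduli = analytic_moduli(MediumModel.newtonian(1.0), np.geomspace(0.1, 100, 40))
        # exact Newtonian moduli have G' = 0 exactly: rejected outright
        with pytest.raises(ValueError):
            fit_maxwell(moduli)
        # a tiny G' floor (numerical dust) converges but is flagged
        floored = ModuliCurves(
            omega=moduli.omega,
            Gp=np.full_like(moduli.omega, 1e-12),
            Gpp=moduli.Gpp,
            alpha=moduli.alpha,
        )
        fit = fit_maxwell(floored)
        assert not fit.ok


class TestPipelineRecovery:
    def test_maxwell_eta_monotone_from_simulation(self):
        medium = MediumModel.maxwell(2.0, 0.8)
        traj = simulate_trajectories(medium, SimConfig(n_beads=150, n_frames=3000, dt=0.015, seed=9))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = smooth_msd(ensemble_msd(traj, lag_grid=default_lag_grid(0.015, 30.0)))
        spec = viscosity_spectrum(gser_moduli(curve))
        # Maxwell check: η(ω) non-increasing up to estimator noise
        # (band edges scatter; the overall trend must fall steadily)
        eta = spec.eta[spec.eta > 0]
        violations = np.diff(np.log(eta)) > 0.1
        assert violations.mean() < 0.15
        assert eta[0] > 10.0 * eta[-1]
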