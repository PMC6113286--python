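"""Fokker-Planck solver, RT likelihoods, and maximum-likelihood fitting."""

import numpy as np
import pytest
from scipy.stats import ks_1samp

from revkernel.ddm import NDTSpec
from revkernel.fpfit import (
    DriftSpec,
    FPSolution,
    SolverAccuracyError,
    _multifeature_negloglik,
    choice_rt_densities,
    energy_to_coherence,
    fit_ml,
    frame_task_params,
    rt_choice_likelihood,
    simulate_coherence_trials,
    simulate_ddm_continuous,
    solve_fp,
)
from revkernel.stimgen import InvalidParameterError


def closed_form_p_upper(mu, B, sigma=1.0):
    if mu == 0:
        return 0.5
    return (1 - np.exp(-2 * mu * B / sigma**2)) / (1 - np.exp(-4 * mu * B / sigma**2))


class TestSolveFP:
    def test_zero_drift_splits_evenly(self):
        fp = solve_fp(0.0, 1.0, dt=5e-4, horizon=10.0)
        assert abs(fp.p_upper - 0.5) < 1e-4

    @pytest.mark.parametrize("mu,B", [(1.5, 1.2), (4.0, 1.0), (-2.0, 0.8)])
    def test_absorption_matches_closed_form(self, mu, B):
        fp = solve_fp(mu, B, dt=5e-4, horizon=10.0)
        assert fp.p_upper == pytest.approx(closed_form_p_upper(mu, B), abs=1e-4)

    def test_mean_decision_time_zero_drift(self):
        # E[T] = B^2 / sigma^2 for the symmetric zero-drift case
        fp = solve_fp(0.0, 1.0, dt=5e-4, horizon=12.0)
        assert fp.mean_decision_time() == pytest.approx(1.0, rel=0.01)

    def test_probability_is_conserved(self):
        fp = solve_fp(2.0, 1.0, dt=1e-3, horizon=8.0)
        assert fp.conservation_error < 1e-6
        assert fp.flux_upper.min() >= 0 and fp.flux_lower.min() >= 0

    def test_too_coarse_grid_raises(self):
        with pytest.raises(SolverAccuracyError, match="Peclet"):
            solve_fp(100.0, 2.0, dt=1e-3, n_grid=33, horizon=1.0)

    def test_time_varying_drift_reduces_to_constant(self):
        mu = np.full(200, 1.0)
        a = solve_fp(mu, 1.0, dt=1e-3, frame_dt=1e-3)
        b = solve_fp(1.0, 1.0, dt=1e-3, horizon=0.2)
        assert np.allclose(a.flux_upper, b.flux_upper)

    def test_matches_monte_carlo_first_passage(self):
        mu, B = 1.5, 1.2
        fp = solve_fp(mu, B, dt=5e-4, horizon=10.0)
        mc = simulate_ddm_continuous(mu, B, n_trials=20_000, dt=1e-3, seed=5)
        cdf_grid = np.cumsum(fp.flux_upper) / fp.flux_upper.sum()
        res = ks_1samp(mc.loc[mc["choice"] == 1, "decision_time"],
                       lambda x: np.interp(x, fp.times, cdf_grid))
        assert res.statistic < 0.03


class TestLikelihood:
    def _toy_flux(self, dt=0.01, t_spike=1.0, horizon=2.0):
        n = int(horizon / dt)
        flux_up = np.zeros(n)
        flux_up[int(t_spike / dt) - 1] = 0.5
        flux_lo = np.zeros(n)
        surv = 1.0 - np.cumsum(flux_up + flux_lo)
        return FPSolution(times=(np.arange(n) + 1) * dt, flux_upper=flux_up,
                          flux_lower=flux_lo, survivor_mass=surv, dt=dt, bound_B=1.0)

    def test_delta_ndt_shifts_flux_exactly(self):
        fp = self._toy_flux()
        t, up, _ = choice_rt_densities(fp, NDTSpec(0.2, 0.0))
        assert t[np.argmax(up)] == pytest.approx(1.2, abs=fp.dt)

    def test_gaussian_ndt_peak_location(self):
        fp = self._toy_flux()
        t, up, _ = choice_rt_densities(fp, NDTSpec(0.2, 0.05))
        assert t[np.argmax(up)] == pytest.approx(1.2, abs=2 * fp.dt)

    def test_densities_integrate_to_one(self):
        fp = solve_fp(0.5, 1.0, dt=1e-3, horizon=12.0)
        t, up, lo = choice_rt_densities(fp, NDTSpec(0.3, 0.1))
        assert (up.sum() + lo.sum()) * fp.dt == pytest.approx(1.0, abs=1e-4)

    def test_rt_beyond_horizon_floors_with_warning(self, caplog):
        import logging

        fp = self._toy_flux()
        with caplog.at_level(logging.WARNING, logger="revkernel.fpfit"):
            ll = rt_choice_likelihood(fp, NDTSpec(0.2, 0.05), np.array([50.0]),
                                      np.array([1]))
        assert ll[0] == pytest.approx(np.log(1e-10))
        assert any("horizon" in rec.message for rec in caplog.records)

    def test_multifeature_likelihood_prefers_true_sensitivities(self):
        rng = np.random.default_rng(2)
        n, F, dt_frame = 60, 20, 8.0 / 75.0
        features = rng.normal(0.0, 0.2, size=(n, F, 3))
        true = dict(B=1.2, gamma_e=10.0, gamma_n=5.0, gamma_m=2.5, T0=0.3,
                    sigma_T0=0.08)
        # generate choices/RTs from the per-trial drift series
        rows = []
        for i in range(n):
            mu = features[i] @ np.array([10.0, 5.0, 2.5])
            steps = np.repeat(mu, int(round(dt_frame / 1e-3)))
            tr = simulate_ddm_continuous(steps, 1.2, n_trials=1, dt=1e-3,
                                         horizon=4.0, ndt=NDTSpec(0.3, 0.08),
                                         seed=1000 + i)
            rows.append((tr["choice"].iloc[0], tr["rt"].iloc[0]))
        choice = np.array([r[0] for r in rows])
        rt = np.array([r[1] for r in rows])
        solver = {"dt": 5e-3, "n_grid": 65}
        nll_true = _multifeature_negloglik(true, rt, choice, features, dt_frame,
                                           "multi_feature", solver)
        for wrong in (
            {**true, "gamma_e": 2.5, "gamma_m": 10.0},  # swapped sensitivities
            {**true, "B": 2.4},
            {**true, "T0": 0.6},
        ):
            assert nll_true < _multifeature_negloglik(
                wrong, rt, choice, features, dt_frame, "multi_feature", solver)


class TestFitML:
    def test_null_sensitivity_is_recovered_as_zero(self):
        trials = simulate_coherence_trials(0.0, 1.2, 0.3, 0.1,
                                           [0.0, 0.256, 0.512], 600, seed=9)
        fit = fit_ml(trials, n_restarts=2, seed=10, maxiter=300)
        assert abs(fit.params["gamma"]) < 2 * fit.se["gamma"]
        assert fit.converged

    def test_drift_spec_validation(self):
        with pytest.raises(InvalidParameterError):
            DriftSpec(mode="coherence")
        with pytest.raises(InvalidParameterError):
            DriftSpec(mode="multi_feature", gamma=1.0)
        spec = DriftSpec(mode="time_varying", gamma=2.0, beta1=0.5)
        assert spec.time_varying
        assert spec.modulation(np.array([1.0]))[0] == pytest.approx(1.5)

    def test_missing_coherence_column_raises(self):
        import pandas as pd

        bad = pd.DataFrame({"choice": [1, 2], "rt": [0.5, 0.6]})
        with pytest.raises(InvalidParameterError):
            fit_ml(bad, n_restarts=1)


class TestFrameTranslation:
    def test_variance_partition_is_consistent(self):
        p = frame_task_params(15.0, 1.2, 0.3, 0.1, sigma_s=0.5, frame_dt=1 / 75)
        dt = 1 / 75
        total = p.sigma_eta**2 + (p.weight.gamma * 0.5) ** 2
        assert p.weight.gamma == pytest.approx(15.0 * dt)
        assert total == pytest.approx(dt)  # sigma_e^2 * dt with sigma_e = 1

    def test_excess_stimulus_variance_raises(self):
        with pytest.raises(InvalidParameterError):
            frame_task_params(15.0, 1.2, 0.3, 0.1, sigma_s=10.0, frame_dt=1 / 75)


class TestPredictKernels:
    def test_face_stream_prediction_returns_one_kernel_per_feature(self):
        from revkernel.fpfit import FitResult, predict_kernels
        from revkernel.stimgen import generate_face_features

        fit = FitResult(
            params=dict(B=1.2, gamma_e=10.0, gamma_n=5.0, gamma_m=2.5,
                        T0=0.3, sigma_T0=0.08),
            loglik=0.0, n_restarts=1, converged=True, mode="multi_feature")
        stream = generate_face_features(3000, 20, mean_morphs=0.0, sd=0.2,
                                        frame_dt=8 / 75, seed=6)
        pred = predict_kernels(fit, stream, seed=7, max_duration=8.0)
        kernels = pred["stimulus"]
        assert [k.feature for k in kernels] == ["eyes", "nose", "mouth"]
        # the most strongly weighted feature has the largest early kernel
        eyes = np.nanmean(kernels[0].values[:3])
        mouth = np.nanmean(kernels[2].values[:3])
        assert eyes > mouth


class TestContinuousSimulator:
    def test_choice_probability_matches_closed_form(self):
        mu, B, n = 1.5, 1.2, 20_000
        mc = simulate_ddm_continuous(mu, B, n_trials=n, dt=1e-3, seed=3)
        p = closed_form_p_upper(mu, B)
        assert abs((mc["choice"] == 1).mean() - p) < 4 * np.sqrt(p * (1 - p) / n)


class TestEnergyToCoherence:
    def test_elementwise_division(self):
        out = energy_to_coherence(np.array([1.0, 0.0, -2.0]), 2.0)
        assert np.allclose(out, [0.5, 0.0, -1.0])

    def test_non_positive_slope_raises(self):
        with pytest.raises(InvalidParameterError):
            energy_to_coherence(np.ones(3), 0.0)
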