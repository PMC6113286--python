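"""Kernel estimation, normalization, distortion, and averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from revkernel import (
    DDMParams,
    NDTSpec,
    UrgencySpec,
    average_kernels,
    compute_kernel,
    distortion,
    generate_gaussian_stimulus,
    normalize_kernel,
    sigma_tot_discrete,
    simulate_bounded_ddm,
)
from revkernel.revcorr import KernelEstimate, mean_bound_height
from revkernel.stimgen import InvalidParameterError, StimulusEnsemble

DT = 1.0 / 75.0


def _ensemble(values):
    values = np.asarray(values, dtype=float)
    return StimulusEnsemble(values=values, frame_dt=DT, sigma_s=1.0,
                            trial_mean=np.zeros(len(values)))


def _trials(choices, rts):
    n = len(choices)
    return pd.DataFrame({
        "trial_id": np.arange(n), "choice": choices,
        "decision_time": rts, "rt": rts,
        "crossed": [True] * n, "censored": [False] * n,
        "terminal_dv": [np.nan] * n,
    })


class TestComputeKernel:
    def test_hand_computed_first_bin(self):
        stim = _ensemble([[1.0], [3.0], [-1.0], [1.0]])
        trials = _trials([1, 1, 2, 2], [DT] * 4)
        k = compute_kernel(stim, trials, window=DT)
        assert k.values[0] == pytest.approx(2.0)

    def test_rt_conditioning_excludes_finished_trials(self):
        # the short-RT choice-2 trial contributes to bin 0 but not bin 1
        stim = _ensemble([[1.0, 2.0], [3.0, 4.0], [-1.0, 0.0], [1.0, 6.0], [-3.0, -8.0]])
        rts = [2 * DT, 2 * DT, 2 * DT, 2 * DT, 0.5 * DT]
        k = compute_kernel(_ensemble(stim.values), _trials([1, 1, 2, 2, 2], rts),
                           window=2 * DT)
        assert k.values[0] == pytest.approx(2.0 - (-1.0))  # -1 = mean(-1, 1, -3)
        assert k.values[1] == pytest.approx(3.0 - 3.0)  # trial 5 excluded
        assert k.n_contributing[0] == 5 and k.n_contributing[1] == 4

    def test_shuffled_labels_give_null_kernel(self, bounded_sim):
        _, trials, stim = bounded_sim
        rng = np.random.default_rng(0)
        shuffled = trials.copy()
        shuffled["choice"] = rng.permutation(shuffled["choice"].to_numpy())
        k = compute_kernel(stim, shuffled)
        ok = np.isfinite(k.values)
        assert np.all(np.abs(k.values[ok]) < 5 * k.sem[ok])
        assert abs(np.nanmean(k.values)) < 4 * np.nanmean(k.sem) / np.sqrt(ok.sum())

    def test_swapping_choice_labels_negates_kernel_exactly(self, bounded_sim):
        _, trials, stim = bounded_sim
        swapped = trials.copy()
        swapped["choice"] = 3 - swapped["choice"]
        k1 = compute_kernel(stim, trials)
        k2 = compute_kernel(stim, swapped)
        assert np.array_equal(k1.values, -k2.values, equal_nan=True)

    def test_contributing_counts_non_increasing(self, bounded_sim):
        _, trials, stim = bounded_sim
        k = compute_kernel(stim, trials)
        assert np.all(np.diff(k.n_contributing) <= 0)
        assert k.window_end == pytest.approx(float(trials["rt"].median()))

    def test_response_alignment_grid_and_final_bin(self, bounded_sim):
        _, trials, stim = bounded_sim
        k = compute_kernel(stim, trials, alignment="response")
        assert k.times[-1] == pytest.approx(-DT)
        assert np.all(np.diff(k.times) > 0)
        # without non-decision time the final pre-response bin is the
        # bound-crossing frame: strongly positive
        assert k.values[-1] > 10 * k.sem[-1]

    def test_single_choice_input_raises(self):
        stim = _ensemble([[1.0], [2.0], [3.0]])
        with pytest.raises(InvalidParameterError):
            compute_kernel(stim, _trials([1, 1, 1], [DT] * 3))

    def test_sparse_bins_are_missing_with_warning(self):
        stim = _ensemble(np.random.default_rng(1).normal(size=(6, 3)))
        rts = [3 * DT, 0.5 * DT, 0.5 * DT, 3 * DT, 0.5 * DT, 0.5 * DT]
        with pytest.warns(UserWarning, match="fewer than 2 trials"):
            k = compute_kernel(_ensemble(stim.values), _trials([1, 1, 1, 2, 2, 2], rts),
                               window=3 * DT)
        assert np.isnan(k.values[1:]).all() and np.isfinite(k.values[0])

    def test_fixed_ndt_trimming_restores_flat_kernel(self):
        # a known, constant non-decision time can be compensated by trimming
        stim = generate_gaussian_stimulus(30_000, 75, sigma_s=1.0, seed=40,
                                          dtype=np.float32)
        params = DDMParams(bound_B=10.0, sigma_eta=1.0, ndt=NDTSpec(0.3, 0.0))
        trials, sf = simulate_bounded_ddm(params, stim, seed=41, max_duration=30.0)
        plain = compute_kernel(sf, trials)
        trimmed = compute_kernel(sf, trials, trim=0.3)

        def trend(k):
            ok = np.isfinite(k.values)
            return stats.spearmanr(k.times[ok], k.values[ok])

        rho_plain, p_plain = trend(plain)
        rho_trim, p_trim = trend(trimmed)
        assert rho_plain < 0 and p_plain < 1e-4  # NDT drags the kernel down
        assert p_trim > 1e-3 and rho_trim > rho_plain  # trimming removes the trend


class TestNormalization:
    def test_bounded_scale_inverts_exactly(self):
        w = np.linspace(0.5, 1.5, 20)
        scale = 2.0 * 1.0 / 30.0
        k = KernelEstimate(times=np.arange(20) * DT, values=scale * w,
                           sem=np.full(20, 0.1), n_contributing=np.full(20, 100),
                           alignment="stimulus", frame_dt=DT)
        kn = normalize_kernel(k, sigma_s=1.0, bound=30.0)
        assert np.allclose(kn.values, w)
        assert kn.normalization == "bounded"

    def test_collapsing_bound_uses_average_height(self):
        urg = UrgencySpec(b=60.0, u_inf=60.0, tau_half=0.4)
        t_end = 0.4
        numeric = integrate.quad(
            lambda t: 60.0 - 60.0 * t / (t + 0.4), 0, t_end)[0] / t_end
        assert mean_bound_height(urg, t_end) == pytest.approx(numeric, rel=1e-10)
        k = KernelEstimate(times=np.arange(10) * DT, values=np.ones(10),
                           sem=np.ones(10), n_contributing=np.full(10, 10),
                           alignment="stimulus", frame_dt=DT)
        kn = normalize_kernel(k, sigma_s=1.0, urgency=urg, median_rt=t_end)
        assert kn.scale_value == pytest.approx(2.0 / numeric)

    def test_unbounded_sigma_tot_discrete_value(self):
        assert sigma_tot_discrete(75, 1.0, 1.0) == pytest.approx(np.sqrt(150.0))
        k = KernelEstimate(times=np.arange(5) * DT, values=np.ones(5),
                           sem=np.ones(5), n_contributing=np.full(5, 10),
                           alignment="stimulus", frame_dt=DT)
        kn = normalize_kernel(k, sigma_s=1.0, sigma_tot=np.sqrt(150.0))
        assert kn.scale_value == pytest.approx(4.0 / (np.sqrt(2 * np.pi * 150.0)))

    def test_missing_context_names_requirement(self):
        k = KernelEstimate(times=np.arange(3) * DT, values=np.ones(3),
                           sem=np.ones(3), n_contributing=np.full(3, 10),
                           alignment="stimulus", frame_dt=DT)
        with pytest.raises(InvalidParameterError, match="bound"):
            normalize_kernel(k, sigma_s=1.0)


class TestDistortion:
    def _kernel(self, values):
        n = len(values)
        return KernelEstimate(times=np.arange(n) * DT, values=np.asarray(values, float),
                              sem=np.ones(n), n_contributing=np.full(n, 10),
                              alignment="stimulus", frame_dt=DT)

    def test_identity_gives_zero(self):
        w = np.linspace(0, 1, 10)
        assert distortion(self._kernel(w), w) == 0.0

    def test_constant_offset(self):
        assert distortion(self._kernel(np.full(8, 1.5)), np.ones(8)) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(2, 30), st.integers(0, 1000))
    def test_matches_elementwise_recomputation(self, n, seed):
        rng = np.random.default_rng(seed)
        k, w = rng.normal(size=n), rng.normal(size=n)
        brute = np.sqrt(sum((a - b) ** 2 for a, b in zip(w, k)) / n)
        assert distortion(self._kernel(k), w) == pytest.approx(brute)

    def test_grid_mismatch_raises(self):
        with pytest.raises(InvalidParameterError):
            distortion(self._kernel(np.ones(5)), np.ones(6))


class TestAverageKernels:
    def _kernel(self, values, alignment="stimulus", window=1.0):
        n = len(values)
        times = (np.arange(n) * DT if alignment == "stimulus"
                 else -(np.arange(n)[::-1] + 1) * DT)
        return KernelEstimate(times=times, values=np.asarray(values, float),
                              sem=np.zeros(n), n_contributing=np.full(n, 10),
                              alignment=alignment, frame_dt=DT, window_end=window)

    def test_identical_kernels_average_to_themselves(self):
        k = self._kernel([1.0, 2.0, 3.0])
        avg = average_kernels([k, k])
        assert np.allclose(avg.values, k.values)
        assert np.allclose(avg.sem, 0.0)

    def test_two_kernel_mean(self):
        avg = average_kernels([self._kernel([0.0, 0.0]), self._kernel([2.0, 2.0])])
        assert np.allclose(avg.values, 1.0)

    def test_window_truncated_to_shortest(self):
        long = self._kernel(np.ones(60), window=0.8)
        short = self._kernel(np.ones(45), window=0.6)
        avg = average_kernels([long, short])
        assert avg.n_bins == 45
        assert avg.window_end == pytest.approx(0.6)

    def test_response_alignment_keeps_bins_near_response(self):
        a = self._kernel([1.0, 2.0, 3.0], alignment="response")
        b = self._kernel([20.0, 30.0], alignment="response")
        avg = average_kernels([a, b])
        assert np.allclose(avg.values, [(2 + 20) / 2, (3 + 30) / 2])
        assert avg.times[-1] == pytest.approx(-DT)

    def test_mixed_alignments_raise(self):
        with pytest.raises(InvalidParameterError):
            average_kernels([self._kernel([1.0]), self._kernel([1.0], "response")])
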