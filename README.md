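# revkernel

Psychophysical reverse correlation under explicit models of the
decision-making process.

Reverse correlation (choice-triggered averaging) is the standard tool for
estimating how observers weight a fluctuating stimulus over time: on neutral
trials, average the stimulus separately by choice and subtract,

    K(t) = E[s(t) | choice 1] − E[s(t) | choice 2].

Under signal-detection-style decision rules this *psychophysical kernel*
recovers the sensory weighting function w(t). But real decisions are made by
accumulating evidence to a bound, reported after variable sensory/motor
delays, and implemented by competing neural integrators — and each of these
mechanisms reshapes the kernel in ways that are easily mistaken for sensory
weight dynamics. `revkernel` is a toolkit for studying, and correcting for,
exactly those distortions. It is aimed at psychophysicists and computational
neuroscientists who use reverse correlation in evidence-accumulation tasks
(random-dot motion, feature-morph categorization, and similar designs).

## What is in the box

- **Simulators** — bounded and unbounded drift-diffusion observers
  (`DV_k = Σ w(t_j) s_j + η_j`, absorbing bounds ±B, optional hyperbolically
  collapsing bound `B(t) = b − u∞ t/(t + τ½)`, Gaussian or gamma
  non-decision time, start-point and drift biases), and two competing
  accumulators with input correlation ρ, leak L, mutual inhibition I, and a
  reflective floor R (`revkernel.ddm`, `revkernel.race`).
- **Stimulus generators** — per-frame Gaussian evidence streams, the
  three-feature morph streams of face-categorization tasks (rejection
  resampling inside ±100% morph), and random-dot kinematograms
  (`revkernel.stimgen`, `revkernel.motion_energy`).
- **Kernel estimation** — stimulus- and response-aligned kernels with the
  exact trial-conditioning of reaction-time tasks (a trial contributes to
  bin t only while its response has not occurred), the analytic
  normalizations `2σ_s²/B` (bounded) and `4σ_s²/(√(2π) σ_tot)` (unbounded)
  that make kernels directly comparable to w(t), and the RMSE distortion
  metric (`revkernel.revcorr`).
- **Model fitting** — a conservative implicit finite-difference
  Fokker–Planck solver for bound-crossing densities, choice/RT likelihoods
  by convolution with the non-decision-time distribution, 10-restart
  maximum-likelihood fits (including time-varying drift
  `μ(t) = γC(1 + β₁t + β₂t²)` and per-trial multi-feature drift), and
  kernel *prediction* from fits — the model-based correction that turns
  kernel distortions into measurements (`revkernel.fpfit`).
- **Motion energy** — opponent spatiotemporal quadrature filtering of dot
  movies, coherence calibration, and conversion of energies to
  coherence-equivalent evidence (`revkernel.motion_energy`).

## Worked example

Simulate a bounded observer with non-decision time and look at its kernels:

```python
import numpy as np
import revkernel as rk

stim = rk.generate_gaussian_stimulus(n_trials=50_000, n_frames=75,
                                     frame_dt=1/75, sigma_s=1.0, seed=7)
params = rk.DDMParams(bound_B=10.0, sigma_eta=1.0, ndt=rk.NDTSpec(0.3, 0.1))
trials, stim_full = rk.simulate_bounded_ddm(params, stim, seed=8)
print(f"median RT: {trials['rt'].median():.3f} s, "
      f"P(choice 1) = {(trials['choice'] == 1).mean():.3f}")

kernel = rk.compute_kernel(stim_full, trials, alignment="stimulus")
kernel = rk.normalize_kernel(kernel, sigma_s=1.0, bound=10.0)
print(f"normalized kernel: first fifth {np.nanmean(kernel.values[:kernel.n_bins//5]):.3f}, "
      f"last fifth {np.nanmean(kernel.values[-kernel.n_bins//5:]):.3f}")

resp = rk.compute_kernel(stim_full, trials, alignment="response")
peak = int(np.nanargmax(resp.values))
print(f"response-aligned kernel peaks {-resp.times[peak]*1000:.0f} ms before the "
      f"response; final bin {resp.values[-1]:.4f} +- {resp.sem[-1]:.4f}")
```

Output:

```
median RT: 0.903 s, P(choice 1) = 0.498
normalized kernel: first fifth 0.917, last fifth 0.560
response-aligned kernel peaks 373 ms before the response; final bin -0.0043 +- 0.0089
```

The generating observer weighted the stimulus *constantly* (w ≡ 1), yet the
stimulus-aligned kernel sags from ≈0.9 toward 0.56 by the median RT, and the
response-aligned kernel collapses to zero just before the report — both pure
decision-process artifacts of bound crossing plus a 300 ± 100 ms
non-decision time. Fitting the diffusion model to the choices and RTs alone
(`revkernel.fpfit.fit_ml`) and forwarding the fitted parameters through
`predict_kernels` reproduces these dynamics quantitatively, which is how the
package distinguishes genuine sensory-weight dynamics from decision
artifacts.

A command-line interface mirrors the library for shell use
(`revkernel simulate|kernel|fit|predict-kernels|dots|energy|fixtures`);
`revkernel fixtures --preset bounded-ndt --seed 1` runs the regime above and
writes trial tables, kernels, and a reproducibility manifest.

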