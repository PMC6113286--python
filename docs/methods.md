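# Methods

This note documents the models implemented in `revkernel`, the conventions
and numerical choices behind them, and what the synthetic-data generators do
and do not emulate.

## The estimator

The psychophysical kernel of a two-alternative task is

    K(t) = E[s(t) | choice 1] - E[s(t) | choice 2],

computed from neutral (mean-zero) trials only. In reaction-time (RT) tasks
the conditioning is on trials whose response has not yet occurred
(`RT >= t`), and kernels are reported up to the median RT so that every bin
is estimated from at least half the trials. Response-aligned kernels index
stimulus frames backward from the frame containing the report, with the RT
rounded down to the onset of the last stimulus frame; the bin at time
`-frame_dt` is the last full frame before that rounded RT. Kernels are
never smoothed. Per-bin uncertainty is the standard error of the difference
of conditional means within an (simulated) observer; `average_kernels`
reports across-observer standard errors and truncates to the shortest
median-RT window.

## Decision models

**Bounded drift diffusion.** The decision variable accumulates
`w(t_k) s_k + eta_k` per stimulus frame, with one independent stimulus draw
`s_k ~ N(C, sigma_s^2)` and one internal-noise draw
`eta_k ~ N(0, sigma_eta^2)` per frame. The stimulus is piecewise-constant
per frame ("one draw per frame", not per-sqrt(dt) white noise) because the
kernel is defined on the frame grid and all analytic scale factors are
stated in these per-frame units with `sigma_s = 1`. The first frame whose
update reaches `+B(t)` / `-B(t)` sets the choice; the DV is absorbed at that
frame with no sub-frame interpolation, which biases decision times and
kernel scales by O(frame): the expected overshoot of a random walk raises
the effective bound by roughly `0.58 * sigma_inc`, i.e. ~3% at `B = 30`
with unit noises. Kernels normalized by `2 sigma_s^2 / B` therefore sit
slightly below the true weight at frame resolution; this is inherent to
frame-resolution simulation, not an estimator defect.

Under a constant bound and weight the normalized stimulus-aligned kernel is
flat at `w`; the analytic scale for a collapsing bound replaces `B` by the
average bound height from stimulus onset to the median RT (closed form for
the hyperbolic profile `B(t) = b - u_inf t / (t + tau_half)`).

**Unbounded integration (fixed duration).** The DV integrates the full
stream; choice is the sign of the terminal DV (exact ties broken at
random). Because only the sum of internal noise matters, it is drawn in
aggregate as `N(0, n_frames * sigma_eta^2)`. The kernel scale is
`4 sigma_s^2 / (sqrt(2 pi) sigma_tot)` with the discrete total variance
`sigma_tot^2 = n_frames sigma_eta^2 + sigma_s^2 sum_k w(t_k)^2`.

**Non-decision time.** Gaussian NDT is truncated at zero and renormalized
(the truncation is negligible at the default 300 +- 100 ms); a
moment-matched gamma family covers right-skewed delays. Stimulus frames
shown between bound crossing and the report are retained in kernel
estimation, emulating the experimenter's ignorance of the internal decision
time.

**Reaction-time horizon.** In RT mode the stimulus stream of undecided
trials is extended on demand up to a hard cap (default 20 s; the validation
runs at `B = 30` raise it to 40-60 s so that fewer than 0.1% of trials are
censored). Censored trials are flagged, counted, and excluded from kernel
estimation.

**Competing accumulators.** Two accumulators receive the stimulus with
opposite signs plus bivariate internal noise whose correlation `rho_prime`
is solved from the desired total-input correlation `rho`. Leak `L` and
mutual inhibition `I` are expressed per frame (the literature regime
`L + I = 0.006` is reproduced at the 13.3-ms frame); the term `v0 (L + I)`
stabilizes the starting point. The reflective floor `R` is implemented as a
projection (clamp after each update), reading the floor of neural firing
rates as a hard lower limit rather than an elastic reflection. Ties (both
accumulators crossing in one frame) are broken by a fair coin and counted.
With `rho = -1` and `L = I = 0` the difference of DVs is exactly a DDM;
when the accumulators start at `v0`, the equivalent DDM bound is the
distance `B - v0`, which is the constant used when normalizing race-model
kernels. Urgency in the race model is a collapsing absorbing bound (the
additive-urgency formulation maps onto it for anti-correlated inputs and is
not implemented separately).

## Fokker-Planck likelihoods and fitting

The bounded-diffusion first-passage problem is solved on a uniform DV grid
over `[-B, +B]` with an implicit (unconditionally stable) finite-difference
step of the probability mass, delta-initialized at 0, Dirichlet-absorbing
at both bounds. Absorbed flux per step is computed from the discrete
boundary-adjacent coefficients so that flux plus surviving mass is conserved
to machine precision (the conservation tolerance enforced is 1e-6; achieved
error is ~1e-12). Central differencing requires the cell Peclet number
`|mu| dx / sigma_e^2 < 1`, which is checked and reported. Defaults for
analysis are a 513-point grid and dt = 0.5 ms; likelihood-based fitting
uses a 129-point grid and dt = 2 ms, which changes log likelihoods by far
less than the optimizer's tolerance while keeping a 10-restart fit under a
minute. Time-varying drift is piecewise constant: per stimulus frame for
per-trial feature streams, and quantized to 25-ms segments for the smooth
polynomial modulation `mu(t) = gamma C (1 + beta1 t + beta2 t^2)`.

RT distributions per choice are the convolution (FFT) of the bound-crossing
flux with the discretized NDT density; observed RTs are binned at the
solver resolution and a likelihood floor of 1e-10 per trial guards against
horizon/rounding underflow. Fitting maximizes the summed log likelihood
over `(B, gamma, T0, sigma_T0)` (plus `beta1, beta2`, or three per-feature
sensitivities) with a derivative-free simplex restarted from 10 randomized
starting points, log-uniform inside documented boxes (`B` in [0.6, 2.5],
`gamma` in [4, 35], `T0` in [0.15, 0.5] s, `sigma_T0` in [0.03, 0.2] s).
`B`, `T0`, `sigma_T0` are optimized on a log scale; sensitivities are
unconstrained so a null sensitivity can be recovered as zero. Standard
errors come from the finite-difference Hessian at the optimum.

The independent stochastic oracle for the solver is a continuous-time Euler
simulation with a Brownian-bridge crossing correction between steps, which
removes the O(sqrt(dt)) first-passage bias of naive Euler.

**Units.** In the coherence task, sensitivity `gamma` is per second per
unit coherence (coherence as a proportion) and the momentary-evidence sd is
fixed at `sigma_e = 1` per sqrt(second), absorbing both stimulus and
internal noise. Translating a fit back to the frame simulator assigns the
stimulus fluctuations (per-frame sd `sigma_s`) the share
`(gamma dt sigma_s)^2` of the per-frame evidence variance `sigma_e^2 dt`
and the remainder to internal noise. In the face task the per-trial feature
fluctuations enter the drift directly, so `sigma_e^2 = sigma_eta^2 = 1`.

## Motion energy

Random-dot kinematograms follow the standard three-set design: 75 Hz video,
each set replotted three frames later (delta-t = 40 ms), 16.7 dots/deg^2/s,
5 deg/s coherent displacement, dots leaving the aperture during coherent
steps wrapping to the opposite side (preserving density; the generator is
otherwise silent on the convention). Spatial sampling is 0.05 deg/pixel;
the circular aperture is applied to the movie, not to filter outputs.

The opponent-energy filters combine even/odd fourth-order Cauchy functions
of space (scale 0.35 deg, transverse Gaussian sd 0.05 deg) with biphasic
temporal impulse responses of rate constant 60/s (t in seconds), composed
as the quadrature pairs `f1 g1 + f2 g2`, `f2 g1 - f1 g2` and their
opposite-direction counterparts. All filters are space-time separable in
their 1-D components, so the implementation convolves with 1-D kernels
along x, y, and t (temporal convolution causal); this is algebraically
identical to convolving with the four 3-D kernels. Supports are truncated
at +-1.5 deg (motion axis), +-0.35 deg (transverse, 7 sd), and 300 ms,
beyond which the filter magnitudes are negligible. Energies are squared,
summed per pair, summed over space, and differenced; the filter axis is
horizontal, with other directions available by orientation swap. Raw
spatial sums are reported without area normalization -- the
coherence-calibration slope absorbs the overall scale. The temporal filters
delay the stimulus-to-energy mapping by ~50 ms (3-4 video frames), measured
as the half-rise latency of the ensemble-mean net energy after a coherence
step.

## Synthetic-data generators and their limits

The generators define the study conditions: per-frame Gaussian evidence
with `sigma_s = 1` (13.3-ms frames) for the evidence-stream experiments;
seven mean morph levels {-50, -30, -14, 0, +14, +30, +50}%, per-frame
feature sd 20% morph, 106.7-ms frames, and rejection-resampling outside
[-100, +100]% (rejecting ~0.18% of draws) for the face task; six coherence
levels {0, 3.2, 6.4, 12.8, 25.6, 51.2}% for the direction task. For the
closed-loop fitting experiments the generating observer uses
`gamma = 15 /s/coherence-unit`, `B = 1.2`, `T0 = 300 ms`,
`sigma_T0 = 100 ms` (sensible magnitudes for trained human observers;
fitted values are not published for this task class) and per-frame
coherence fluctuations of sd 0.5, chosen so stimulus fluctuations carry a
realistic majority share of the momentary-evidence variance.

What the generators do not emulate: sequential dependencies across trials,
lapses and attentional drift, non-Gaussian internal noise, spatial
nonuniformity of the dot field, and the rendering of actual face images
(only the per-frame morph values are modeled). Passing tests therefore
establishes internal consistency of estimator, models, and fitter under the
stated stochastic assumptions -- not robustness to these unmodeled features
of real data.

## Problem sizes and reproducibility

Kernel-recovery validations use 1-2 x 10^5 trials (the package's chosen
desk-scale default; figure-grade studies would use 10^6), parameter
recovery 3000 trials, kernel prediction 10^5 fresh streams, and the
motion-energy calibration 50 movies per coherence at a 3-deg aperture. At
2 x 10^5 trials the per-bin Monte-Carlo noise of a normalized bounded-DDM
kernel at `B = 30` is ~0.07, so root-mean-square kernel-weight distortions
below ~0.075 at that scale are indistinguishable from the sampling floor;
distortion comparisons across conditions should use matched trial counts.
Every stochastic routine takes a seed; substreams for stimulus, internal
noise, non-decision time, and tie-breaks are spawned from it, so identical
(parameters, seed) pairs give bit-identical outputs. Large simulations
store stimuli as float32 (a 2 x 10^5 x 3000-frame ensemble is ~2.4 GB).

## Known limitations

- Frame-resolution absorption biases kernel scales by O(frame) (see above);
  comparisons against analytic scale factors are accurate to ~3% at B = 30
  and ~8% at B = 10 with unit per-frame noise.
- The per-trial Fokker-Planck likelihood (face task) solves one equation
  per trial and is 1-2 orders of magnitude slower than the per-condition
  path; it is practical for thousands of trials, not millions.
- The race model fixes two accumulators; pools of more than two and
  self-excitation are out of scope (leak is constrained non-negative).
- The motion-energy filters use the published constants; no fitting of
  filter parameters to neural data is attempted, and absolute energy units
  are arbitrary (calibration to coherence units is the supported use).
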