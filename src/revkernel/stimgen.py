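"""Stochastic stimulus ensembles and sensory weight functions.

All simulators and kernel estimators in this package consume the containers
defined here.  The central abstraction is a trials x frames matrix of signed
evidence values (``StimulusEnsemble``): each row is one trial's sequence of
independent Gaussian draws, held constant within a stimulus frame.  Evidence
is dimensionless (e.g. % motion coherence or % morph level); time is in
seconds throughout the package.

Two frame durations recur because they correspond to the display regimes the
package emulates: 13.3 ms (75 Hz video, random-dot motion) and 106.7 ms
(masked face stimuli).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FRAME_DT_DOTS",
    "FRAME_DT_FACES",
    "MORPH_LEVELS",
    "StimulusEnsemble",
    "WeightSpec",
    "FaceFeatureStream",
    "generate_gaussian_stimulus",
    "evaluate_weights",
    "generate_face_features",
    "expected_rejection_fraction",
]

#: Frame duration of a 75 Hz display (random-dot stimuli), seconds.
FRAME_DT_DOTS = 1.0 / 75.0
#: Frame duration of the masked face stream (one face per 8 video frames), seconds.
FRAME_DT_FACES = 8.0 / 75.0
#: Mean morph strengths (% morph) used in the face-categorization regime.
MORPH_LEVELS = (-50.0, -30.0, -14.0, 0.0, 14.0, 30.0, 50.0)


class InvalidParameterError(ValueError):
    """Raised when generator or model parameters are out of their domain."""


@dataclass
class StimulusEnsemble:
    """Trials x frames matrix of signed evidence values.

    Attributes
    ----------
    values : ndarray, shape (n_trials, n_frames)
        Per-frame evidence. ``values[i, k]`` is held constant during frame
        ``k`` of trial ``i`` (piecewise-constant stimulus, one independent
        draw per frame).
    frame_dt : float
        Frame duration in seconds.
    sigma_s : float
        Per-frame standard deviation of the evidence fluctuations.
    trial_mean : ndarray, shape (n_trials,)
        Mean evidence strength of each trial (signed stimulus strength C).
    seed : int or None
        Seed used to generate the ensemble (None for hand-built ensembles).
    """

    values: np.ndarray
    frame_dt: float
    sigma_s: float
    trial_mean: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise InvalidParameterError("values must be 2-D (trials x frames)")
        if not np.isfinite(self.values).all():
            raise InvalidParameterError("stimulus values must be finite")
        if self.frame_dt <= 0:
            raise InvalidParameterError("frame_dt must be positive")
        self.trial_mean = np.broadcast_to(
            np.asarray(self.trial_mean, dtype=float), (self.values.shape[0],)
        ).copy()

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_dt

    def frame_times(self) -> np.ndarray:
        """Onset time of each frame, in seconds."""
        return np.arange(self.n_frames) * self.frame_dt


@dataclass
class WeightSpec:
    """Sensory weight function w(t).

    ``constant``: w(t) = gamma.
    ``polynomial``: w(t) = gamma * (1 + beta1 * t + beta2 * t**2), the linear
    plus quadratic temporal modulation used to probe weight dynamics.
    ``sinusoid``: w(t) = gamma + amplitude * sin(2 pi t / period + phase).
    """

    kind: str = "constant"
    gamma: float = 1.0
    beta1: float = 0.0
    beta2: float = 0.0
    amplitude: float = 0.0
    period: float = 1.0
    phase: float = 0.0

    def __call__(self, times: np.ndarray) -> np.ndarray:
        return evaluate_weights(self, times)


def evaluate_weights(spec: WeightSpec, times: np.ndarray) -> np.ndarray:
    """Evaluate a weight specification on a vector of times (seconds)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("times must be non-negative")
    if spec.kind == "constant":
        return np.full_like(t, spec.gamma)
    if spec.kind == "polynomial":
        return spec.gamma * (1.0 + spec.beta1 * t + spec.beta2 * t**2)
    if spec.kind == "sinusoid":
        if spec.period <= 0:
            raise InvalidParameterError("sinusoid period must be positive")
        return spec.gamma + spec.amplitude * np.sin(2 * np.pi * t / spec.period + spec.phase)
    raise InvalidParameterError(f"unknown weight kind {spec.kind!r}")


@dataclass
class FaceFeatureStream:
    """Per-trial, per-frame morph levels of the three informative face features.

    ``values`` has shape (n_trials, n_frames, 3) with features ordered
    (eyes, nose, mouth).  All values lie in [-100, 100] % morph; draws are
    Gaussian around the trial mean with rejection-resampling of out-of-range
    samples.
    """

    values: np.ndarray
    mean_morph: np.ndarray
    sd: float
    frame_dt: float
    feature_names: tuple[str, str, str] = ("eyes", "nose", "mouth")
    rejected_fraction: float = 0.0
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def feature_ensemble(self, feature: int | str) -> StimulusEnsemble:
        """View one feature as a StimulusEnsemble (for kernel estimation)."""
        if isinstance(feature, str):
            feature = self.feature_names.index(feature)
        return StimulusEnsemble(
            values=self.values[:, :, feature],
            frame_dt=self.frame_dt,
            sigma_s=self.sd,
            trial_mean=self.mean_morph,
            seed=self.seed,
        )


def generate_gaussian_stimulus(
    n_trials: int,
    n_frames: int,
    frame_dt: float = FRAME_DT_DOTS,
    sigma_s: float = 1.0,
    trial_means: float | np.ndarray = 0.0,
    seed: int | np.random.SeedSequence | None = None,
    dtype=np.float64,
) -> StimulusEnsemble:
    """Draw an ensemble of i.i.d. Gaussian evidence streams.

    ``values[i, k] ~ Normal(trial_means[i], sigma_s**2)`` independently across
    trials and frames.  Reproducible for a fixed seed.
    """
    if n_trials < 1 or n_frames < 1:
        raise InvalidParameterError("n_trials and n_frames must be >= 1")
    if sigma_s < 0:
        raise InvalidParameterError("sigma_s must be non-negative")
    if frame_dt <= 0:
        raise InvalidParameterError("frame_dt must be positive")
    rng = np.random.default_rng(seed)
    means = np.broadcast_to(np.asarray(trial_means, dtype=float), (n_trials,))
    if sigma_s == 0.0:
        values = np.repeat(means[:, None], n_frames, axis=1).astype(dtype)
    else:
        values = rng.standard_normal((n_trials, n_frames), dtype=np.float64 if dtype is np.float64 else np.float32)
        values *= sigma_s
        values += means[:, None]
        values = values.astype(dtype, copy=False)
    return StimulusEnsemble(
        values=values,
        frame_dt=frame_dt,
        sigma_s=float(sigma_s),
        trial_mean=means,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def expected_rejection_fraction(
    means: np.ndarray | tuple = MORPH_LEVELS,
    sd: float = 20.0,
    lo: float = -100.0,
    hi: float = 100.0,
    weights: np.ndarray | None = None,
) -> float:
    """Analytic probability that a Gaussian feature draw falls outside range.

    Averages the out-of-range mass of Normal(m, sd^2) over the condition
    means ``m`` (uniformly unless ``weights`` gives condition frequencies).
    """
    means = np.asarray(means, dtype=float)
    if sd == 0:
        return 0.0
    p = stats.norm.cdf((lo - means) / sd) + stats.norm.sf((hi - means) / sd)
    if weights is None:
        return float(p.mean())
    weights = np.asarray(weights, dtype=float)
    return float(np.average(p, weights=weights))


def generate_face_features(
    n_trials: int,
    n_frames: int,
    mean_morphs: float | np.ndarray = 0.0,
    sd: float = 20.0,
    frame_dt: float = FRAME_DT_FACES,
    seed: int | np.random.SeedSequence | None = None,
    lo: float = -100.0,
    hi: float = 100.0,
) -> FaceFeatureStream:
    """Sample the three face features with rejection-resampling.

    Each feature value is drawn Normal(mean, sd^2); draws outside
    ``[lo, hi]`` are replaced with new samples until inside the range (the
    distribution is therefore a truncated Gaussian).  The fraction of
    initially rejected draws is recorded on the returned stream.
    """
    if n_trials < 1 or n_frames < 1:
        raise InvalidParameterError("n_trials and n_frames must be >= 1")
    if sd < 0:
        raise InvalidParameterError("sd must be non-negative")
    means = np.broadcast_to(np.asarray(mean_morphs, dtype=float), (n_trials,))
    if np.any(np.abs(means) > hi):
        raise InvalidParameterError("mean morph levels must lie within the morph range")
    rng = np.random.default_rng(seed)
    shape = (n_trials, n_frames, 3)
    if sd == 0.0:
        values = np.broadcast_to(means[:, None, None], shape).copy()
        rejected = 0
        total = int(np.prod(shape))
    else:
        values = means[:, None, None] + sd * rng.standard_normal(shape)
        total = int(np.prod(shape))
        bad = (values < lo) | (values > hi)
        rejected = int(bad.sum())
        # Resample only the out-of-range entries until all are inside.
        while bad.any():
            idx = np.nonzero(bad)
            values[idx] = means[idx[0]] + sd * rng.standard_normal(idx[0].size)
            bad = (values < lo) | (values > hi)
    return FaceFeatureStream(
        values=values,
        mean_morph=means.copy(),
        sd=float(sd),
        frame_dt=frame_dt,
        rejected_fraction=rejected / total,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
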