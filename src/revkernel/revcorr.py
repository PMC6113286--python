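"""Psychophysical kernel estimation, normalization, and distortion metrics.

The psychophysical kernel is the time-resolved difference of mean stimulus
fluctuations conditioned on the two choices,

    K(t) = E[s(t) | choice 1] - E[s(t) | choice 2],

estimated only from neutral (mean-zero) trials.  In reaction-time tasks a
trial contributes to bin ``t`` only while its response has not yet occurred
(the conditioning is on RT >= t), and kernels are reported up to the median
RT so that at least half of the trials contribute to every bin.  Kernels can
also be aligned to the response, counting stimulus frames backward from the
frame containing the report.

Under a bounded accumulation model with constant bound B the kernel equals
(2 sigma_s^2 / B) w(t); under unbounded integration of a fixed-duration
stimulus it equals (4 sigma_s^2 / (sqrt(2 pi) sigma_tot)) w(t).  Dividing by
these scale factors makes kernels directly comparable to the sensory weight
function w(t); the residual root-mean-square difference is the distortion.

No smoothing is ever applied to kernels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ddm import UrgencySpec
from .stimgen import FaceFeatureStream, InvalidParameterError, StimulusEnsemble

__all__ = [
    "KernelEstimate",
    "compute_kernel",
    "normalize_kernel",
    "distortion",
    "average_kernels",
    "sigma_tot_discrete",
    "mean_bound_height",
]

logger = logging.getLogger(__name__)


@dataclass
class KernelEstimate:
    """Time-binned psychophysical kernel with per-bin uncertainty.

    ``times`` are bin onsets in seconds: non-negative frame onsets for
    stimulus alignment, negative offsets (the bin ending at the response has
    onset -frame_dt) for response alignment.  ``normalization`` is one of
    ``raw``, ``bounded``, ``unbounded``; ``scale_value`` records the divisor
    that has been applied.
    """

    times: np.ndarray
    values: np.ndarray
    sem: np.ndarray
    n_contributing: np.ndarray
    alignment: str
    frame_dt: float
    normalization: str = "raw"
    scale_value: float = 1.0
    window_end: float = np.nan
    feature: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "value": self.values,
                "sem": self.sem,
                "n": self.n_contributing,
            }
        )

    @property
    def n_bins(self) -> int:
        return len(self.times)


def _window_frames(window: float, dt: float) -> int:
    return int(np.ceil(window / dt - 1e-9))


def _single_kernel(
    values: np.ndarray,
    frame_dt: float,
    trials: pd.DataFrame,
    alignment: str,
    window: float | None,
    inclusion: str,
    trim: float,
    feature: str | None,
) -> KernelEstimate:
    rt = trials["rt"].to_numpy(dtype=float)
    choice = trials["choice"].to_numpy()
    c1 = choice == 1
    c2 = choice == 2
    if not c1.any() or not c2.any():
        raise InvalidParameterError("kernel estimation requires trials of both choices")
    n, F = values.shape
    dt = frame_dt
    if window is None:
        window = float(np.median(rt))
    n_bins = min(_window_frames(window, dt), F)
    if n_bins < 1:
        raise InvalidParameterError("window shorter than one stimulus frame")

    K = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    n_contrib = np.zeros(n_bins, dtype=np.int64)
    rows = np.arange(n)
    short_bins = 0

    for k in range(n_bins):
        if alignment == "stimulus":
            onset = k * dt
            cutoff = onset + (dt if inclusion == "offset" else 0.0)
            include = (rt - trim) >= cutoff - 1e-12
            col = values[:, k]
        else:  # response-aligned, lag k frames before the last full frame
            resp_frame = np.floor(rt / dt + 1e-9).astype(np.int64)
            col_idx = resp_frame - 1 - k
            include = (col_idx >= 0) & (col_idx < F)
            col = values[rows, np.clip(col_idx, 0, F - 1)]
        m1 = include & c1
        m2 = include & c2
        n1, n2 = int(m1.sum()), int(m2.sum())
        n_contrib[k] = n1 + n2
        if n1 < 2 or n2 < 2:
            short_bins += 1
            continue
        x1 = col[m1].astype(np.float64)
        x2 = col[m2].astype(np.float64)
        K[k] = x1.mean() - x2.mean()
        sem[k] = np.sqrt(x1.var(ddof=1) / n1 + x2.var(ddof=1) / n2)

    if short_bins:
        warnings.warn(
            f"{short_bins} kernel bins had fewer than 2 trials on one choice and are missing",
            stacklevel=3,
        )
    if alignment == "stimulus":
        times = np.arange(n_bins) * dt
    else:
        # ascending times from -window to -dt; values computed by lag, so flip
        times = -(np.arange(n_bins)[::-1] + 1) * dt
        K, sem, n_contrib = K[::-1].copy(), sem[::-1].copy(), n_contrib[::-1].copy()
    return KernelEstimate(
        times=times,
        values=K,
        sem=sem,
        n_contributing=n_contrib,
        alignment=alignment,
        frame_dt=dt,
        window_end=float(window),
        feature=feature,
    )


def compute_kernel(
    stim: StimulusEnsemble | FaceFeatureStream,
    trials: pd.DataFrame,
    alignment: str = "stimulus",
    window: float | None = None,
    inclusion: str = "onset",
    trim: float = 0.0,
):
    """Estimate the psychophysical kernel of an ensemble of neutral trials.

    Parameters
    ----------
    stim
        Stimulus ensemble (or three-feature face stream, in which case one
        kernel per feature is returned).  Only mean-zero (0% strength) trials
        should be supplied.
    trials
        Outcome table with ``choice`` and ``rt`` columns (censored trials are
        dropped with a log message).
    alignment
        ``"stimulus"``: bin ``k`` averages frame ``k`` over trials whose RT
        has not yet occurred (RT >= frame onset by default; set
        ``inclusion="offset"`` to require RT >= frame offset).
        ``"response"``: frames are indexed backward from the response, with
        the RT rounded down to the onset of the last stimulus frame; the bin
        at time -frame_dt is the last full frame before that rounded RT.
    window
        Kernel extent in seconds; defaults to the median RT of the supplied
        trials.
    trim
        Exclude the final ``trim`` seconds of each trial's stimulus (used to
        compensate a known, fixed non-decision time).
    """
    if alignment not in ("stimulus", "response"):
        raise InvalidParameterError(f"unknown alignment {alignment!r}")
    if inclusion not in ("onset", "offset"):
        raise InvalidParameterError(f"unknown inclusion rule {inclusion!r}")
    if "censored" in trials.columns and trials["censored"].any():
        n_cens = int(trials["censored"].sum())
        logger.info("excluding %d censored trials from kernel estimation", n_cens)
        trials = trials.loc[~trials["censored"]]

    if isinstance(stim, FaceFeatureStream):
        keep = trials["trial_id"].to_numpy()
        return [
            _single_kernel(
                stim.values[keep, :, f],
                stim.frame_dt,
                trials,
                alignment,
                window,
                inclusion,
                trim,
                feature=name,
            )
            for f, name in enumerate(stim.feature_names)
        ]
    keep = trials["trial_id"].to_numpy()
    return _single_kernel(
        stim.values[keep], stim.frame_dt, trials, alignment, window, inclusion, trim, None
    )


def sigma_tot_discrete(
    n_frames: int, sigma_eta: float, sigma_s: float, weights: np.ndarray | float = 1.0
) -> float:
    """Terminal-DV standard deviation of unbounded integration (per-frame units).

    sigma_tot^2 = n_frames * sigma_eta^2 + sigma_s^2 * sum_k w_k^2.
    """
    w = np.broadcast_to(np.asarray(weights, dtype=float), (n_frames,))
    return float(np.sqrt(n_frames * sigma_eta**2 + sigma_s**2 * np.sum(w**2)))


def mean_bound_height(urgency: UrgencySpec, t_end: float) -> float:
    """Time-average of the collapsing bound over [0, t_end] (closed form)."""
    if t_end <= 0:
        raise InvalidParameterError("t_end must be positive")
    b, u, tau = urgency.b, urgency.u_inf, urgency.tau_half
    return b - u * (1.0 - (tau / t_end) * np.log1p(t_end / tau))


def normalize_kernel(
    kernel: KernelEstimate,
    sigma_s: float,
    bound: float | None = None,
    urgency: UrgencySpec | None = None,
    sigma_tot: float | None = None,
    median_rt: float | None = None,
) -> KernelEstimate:
    """Divide a raw kernel by the model scale factor so it estimates w(t).

    Exactly one model context applies: ``sigma_tot`` for unbounded
    integration (scale 4 sigma_s^2 / (sqrt(2 pi) sigma_tot)); ``bound`` for a
    constant absorbing bound (scale 2 sigma_s^2 / B); ``urgency`` for a
    collapsing bound, where B is replaced by the average bound height from
    stimulus onset to the median RT (``median_rt``, defaulting to the
    kernel's window).
    """
    if kernel.normalization != "raw":
        raise InvalidParameterError("kernel is already normalized")
    if sigma_tot is not None:
        scale = 4.0 * sigma_s**2 / (np.sqrt(2.0 * np.pi) * sigma_tot)
        label = "unbounded"
    elif urgency is not None:
        t_end = median_rt if median_rt is not None else kernel.window_end
        if not np.isfinite(t_end):
            raise InvalidParameterError("urgency normalization requires median_rt")
        scale = 2.0 * sigma_s**2 / mean_bound_height(urgency, t_end)
        label = "bounded"
    elif bound is not None:
        scale = 2.0 * sigma_s**2 / bound
        label = "bounded"
    else:
        raise InvalidParameterError(
            "normalization requires one of: bound (constant-bound model), "
            "urgency (collapsing bound), sigma_tot (unbounded model)"
        )
    return replace(
        kernel,
        values=kernel.values / scale,
        sem=kernel.sem / scale,
        normalization=label,
        scale_value=float(scale),
    )


def distortion(kernel: KernelEstimate, weights: np.ndarray) -> float:
    """Root-mean-square difference between a normalized kernel and w(t).

    Missing bins (insufficient trials) are excluded from the average.  The
    weight vector must be given on the kernel's time grid.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != kernel.values.shape:
        raise InvalidParameterError(
            f"weight grid {w.shape} does not match kernel grid {kernel.values.shape}"
        )
    ok = np.isfinite(kernel.values)
    if not ok.any():
        raise InvalidParameterError("kernel has no valid bins")
    return float(np.sqrt(np.mean((w[ok] - kernel.values[ok]) ** 2)))


def average_kernels(kernels: list[KernelEstimate]) -> KernelEstimate:
    """Unweighted across-subject average of kernels on a common grid.

    All kernels must share alignment and bin width.  The output window is
    truncated to the shortest individual window (for response alignment, the
    bins closest to the response are kept).  The reported sem is the standard
    error across subjects.
    """
    if not kernels:
        raise InvalidParameterError("need at least one kernel")
    k0 = kernels[0]
    if any(k.alignment != k0.alignment for k in kernels):
        raise InvalidParameterError("cannot average kernels with mixed alignments")
    if any(not np.isclose(k.frame_dt, k0.frame_dt) for k in kernels):
        raise InvalidParameterError("cannot average kernels with different bin widths")
    n_bins = min(k.n_bins for k in kernels)
    if k0.alignment == "stimulus":
        sl = slice(0, n_bins)
    else:
        sl = slice(-n_bins, None)
    stack = np.vstack([k.values[sl] for k in kernels])
    mean = stack.mean(axis=0)
    S = len(kernels)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(S) if S > 1 else np.zeros(n_bins)
    return KernelEstimate(
        times=k0.times[sl].copy(),
        values=mean,
        sem=sem,
        n_contributing=np.sum([k.n_contributing[sl] for k in kernels], axis=0),
        alignment=k0.alignment,
        frame_dt=k0.frame_dt,
        normalization=k0.normalization,
        scale_value=np.nan,
        window_end=min(k.window_end for k in kernels),
    )
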