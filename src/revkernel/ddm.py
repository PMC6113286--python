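"""Drift-diffusion decision simulators.

Decisions are modeled as accumulation of weighted sensory evidence plus
internal noise.  The decision variable after frame ``k`` is

    DV_k = start_point + drift_offset * t_k + sum_{j<=k} [ w(t_j) s_j + eta_j ]

with one stimulus draw ``s_j`` and one internal-noise draw
``eta_j ~ N(0, sigma_eta^2)`` per frame (Euler accumulation at stimulus-frame
resolution; all noise standard deviations are per frame).  In the bounded
(reaction-time) variant the first frame whose update pushes the DV to the
upper bound +B(t) yields choice 1, the lower bound -B(t) choice 2, and the
reported reaction time adds a random non-decision time.  The DV is absorbed
at the first frame whose update crosses the bound; there is no sub-frame
interpolation, so decision times carry an O(frame) discretization bias.

The unbounded variant integrates for the full fixed stimulus duration and
chooses by the sign of the terminal DV.

Urgency is modeled as a hyperbolically collapsing bound
``B(t) = b - u_inf * t / (t + tau_half)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .stimgen import InvalidParameterError, StimulusEnsemble, WeightSpec, evaluate_weights

__all__ = [
    "UrgencySpec",
    "NDTSpec",
    "DDMParams",
    "TrialOutcome",
    "bound_profile",
    "bound_crossing_prob",
    "sample_ndt",
    "simulate_bounded_ddm",
    "simulate_unbounded_ddm",
]

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ["trial_id", "choice", "decision_time", "rt", "crossed", "censored", "terminal_dv"]


class TrialOutcome(NamedTuple):
    """Single-trial view of a simulated (or observed) decision."""

    choice: int
    decision_time: float
    rt: float
    crossed: bool
    terminal_dv: float


@dataclass
class UrgencySpec:
    """Hyperbolic bound collapse: B(t) = b - u_inf * t / (t + tau_half)."""

    b: float
    u_inf: float
    tau_half: float

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise InvalidParameterError("initial bound height b must be positive")
        if not 0 <= self.u_inf <= self.b:
            raise InvalidParameterError("u_inf must lie in [0, b]")
        if self.tau_half <= 0:
            raise InvalidParameterError("tau_half must be positive")


def bound_profile(t: float | np.ndarray, spec: UrgencySpec) -> float | np.ndarray:
    """Bound height at time(s) t (seconds); monotone non-increasing."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be non-negative")
    out = spec.b - spec.u_inf * t / (t + spec.tau_half)
    return float(out) if out.ndim == 0 else out


@dataclass
class NDTSpec:
    """Non-decision time distribution (sensory + motor delays).

    ``gaussian``: Normal(mean_T0, sd_T0^2) truncated at 0 and renormalized.
    ``gamma``: moment-matched gamma (shape (mean/sd)^2, scale sd^2/mean),
    a right-skewed alternative with skewness 2*sd/mean.
    """

    mean_T0: float = 0.3
    sd_T0: float = 0.1
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.mean_T0 < 0 or self.sd_T0 < 0:
            raise InvalidParameterError("non-decision time mean and sd must be >= 0")
        if self.family not in ("gaussian", "gamma"):
            raise InvalidParameterError(f"unknown non-decision time family {self.family!r}")
        if self.family == "gamma" and self.sd_T0 > 0 and self.mean_T0 <= 0:
            raise InvalidParameterError("gamma non-decision time requires mean_T0 > 0")


def sample_ndt(spec: NDTSpec, n: int, seed=None) -> np.ndarray:
    """Draw n non-decision times (seconds, all >= 0)."""
    rng = np.random.default_rng(seed)
    if spec.sd_T0 == 0.0:
        return np.full(n, spec.mean_T0)
    if spec.family == "gaussian":
        a = -spec.mean_T0 / spec.sd_T0  # truncate at zero
        return stats.truncnorm.rvs(
            a, np.inf, loc=spec.mean_T0, scale=spec.sd_T0, size=n, random_state=rng
        )
    shape = (spec.mean_T0 / spec.sd_T0) ** 2
    scale = spec.sd_T0**2 / spec.mean_T0
    return rng.gamma(shape, scale, size=n)


@dataclass
class DDMParams:
    """Parameterization of the drift-diffusion simulators.

    ``bound_B`` is the absorbing bound in accumulated-evidence units; under a
    collapsing bound (``urgency``) the profile's initial height replaces it.
    ``sigma_eta`` is the per-frame internal-noise sd, ``start_point`` a static
    offset of the starting DV (bias), ``drift_offset`` an additive drift bias
    in evidence units per second.
    """

    bound_B: float | None = None
    sigma_eta: float = 1.0
    start_point: float = 0.0
    drift_offset: float = 0.0
    urgency: UrgencySpec | None = None
    ndt: NDTSpec | None = None
    weight: WeightSpec = field(default_factory=WeightSpec)

    def __post_init__(self) -> None:
        if self.bound_B is None and self.urgency is None:
            raise InvalidParameterError("either bound_B or an urgency profile is required")
        if self.sigma_eta < 0:
            raise InvalidParameterError("sigma_eta must be non-negative")
        b0 = self.initial_bound
        if b0 <= 0:
            raise InvalidParameterError("bound height must be positive")
        if abs(self.start_point) >= b0:
            raise InvalidParameterError("|start_point| must be smaller than the bound")

    @property
    def initial_bound(self) -> float:
        return self.urgency.b if self.urgency is not None else float(self.bound_B)

    def bound_at(self, times: np.ndarray) -> np.ndarray:
        """Bound height at the given times (seconds)."""
        times = np.asarray(times, dtype=float)
        if self.urgency is not None:
            return np.asarray(bound_profile(times, self.urgency))
        return np.full(times.shape, float(self.bound_B))


def bound_crossing_prob(dv_after_sample: float | np.ndarray, B: float) -> float | np.ndarray:
    """Probability of eventual upper-bound absorption from an interior DV.

    With zero net drift the absorption probability is the relative distance
    from the lower bound, (B + dv) / (2B).
    """
    dv = np.asarray(dv_after_sample, dtype=float)
    if B <= 0:
        raise InvalidParameterError("bound must be positive")
    if np.any(np.abs(dv) > B):
        raise InvalidParameterError("decision variable outside [-B, B]")
    out = (B + dv) / (2.0 * B)
    return float(out) if out.ndim == 0 else out


def _rng_streams(seed, n: int):
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def simulate_bounded_ddm(
    params: DDMParams,
    stim: StimulusEnsemble,
    seed=None,
    mode: str = "rt",
    max_duration: float = 20.0,
    block_frames: int = 256,
) -> tuple[pd.DataFrame, StimulusEnsemble]:
    """Simulate bounded-accumulation decisions on a stimulus ensemble.

    In ``mode="rt"`` the stimulus stream of undecided trials is extended on
    demand (fresh draws with the ensemble's sigma_s and trial means) up to
    ``max_duration`` seconds; trials that never cross are censored with
    ``crossed=False`` and a logged count.  In ``mode="fixed"`` integration
    stops at the end of the given stream; if the DV crossed a bound earlier it
    freezes there, otherwise the choice is the sign of the terminal DV.

    Returns the per-trial outcome table and the (possibly extended) stimulus
    ensemble, which retains every frame shown -- including frames after the
    decision -- because kernel estimation must emulate the experimenter's
    ignorance of the internal decision time.
    """
    if mode not in ("rt", "fixed"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    rng_stim, rng_eta, rng_misc = _rng_streams(seed, 3)
    n, dt = stim.n_trials, stim.frame_dt
    if mode == "rt":
        horizon = max(stim.n_frames, int(np.ceil(max_duration / dt - 1e-9)))
    else:
        horizon = stim.n_frames

    if horizon > stim.n_frames:
        values = np.zeros((n, horizon), dtype=stim.values.dtype)
        values[:, : stim.n_frames] = stim.values
    else:
        values = stim.values

    w = evaluate_weights(params.weight, np.arange(horizon) * dt)
    bound = params.bound_at((np.arange(horizon) + 1) * dt)

    dv = np.full(n, float(params.start_point))
    choice = np.zeros(n, dtype=np.int64)
    dec_frame = np.full(n, horizon - 1, dtype=np.int64)
    crossed = np.zeros(n, dtype=bool)
    active = np.arange(n)

    for f0 in range(0, horizon, block_frames):
        f1 = min(f0 + block_frames, horizon)
        if f1 > stim.n_frames:  # extend stimulus for still-active trials
            g0 = max(f0, stim.n_frames)
            fresh = rng_stim.standard_normal((active.size, f1 - g0))
            fresh *= stim.sigma_s
            fresh += stim.trial_mean[active, None]
            values[active[:, None], np.arange(g0, f1)[None, :]] = fresh
        sb = values[active, f0:f1].astype(np.float64)
        inc = w[f0:f1][None, :] * sb
        if params.sigma_eta > 0:
            inc += params.sigma_eta * rng_eta.standard_normal(inc.shape)
        if params.drift_offset != 0.0:
            inc += params.drift_offset * dt
        np.cumsum(inc, axis=1, out=inc)
        inc += dv[active, None]
        up = inc >= bound[f0:f1]
        lo = inc <= -bound[f0:f1]
        hit = up | lo
        anyhit = hit.any(axis=1)
        rows = np.nonzero(anyhit)[0]
        if rows.size:
            first = np.argmax(hit[rows], axis=1)
            idx = active[rows]
            choice[idx] = np.where(up[rows, first], 1, 2)
            dec_frame[idx] = f0 + first
            crossed[idx] = True
        surv = ~anyhit
        dv[active[surv]] = inc[surv, -1]
        active = active[surv]
        if active.size == 0:
            break

    terminal_dv = np.full(n, np.nan)
    censored = np.zeros(n, dtype=bool)
    if active.size:
        terminal_dv[active] = dv[active]
        signs = dv[active]
        tie = signs == 0
        if tie.any():
            signs = signs.copy()
            signs[tie] = rng_misc.choice([-1.0, 1.0], size=int(tie.sum()))
        choice[active] = np.where(signs > 0, 1, 2)
        if mode == "rt":
            censored[active] = True
            logger.warning(
                "%d of %d trials did not cross a bound within %.1f s and were censored",
                active.size, n, horizon * dt,
            )

    decision_time = (dec_frame + 1) * dt
    rt = decision_time.astype(float)
    if params.ndt is not None:
        rt = rt + sample_ndt(params.ndt, n, seed=rng_misc)

    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "choice": choice,
            "decision_time": decision_time,
            "rt": rt,
            "crossed": crossed,
            "censored": censored,
            "terminal_dv": terminal_dv,
        }
    )
    stim_out = stim if horizon == stim.n_frames else StimulusEnsemble(
        values=values, frame_dt=dt, sigma_s=stim.sigma_s,
        trial_mean=stim.trial_mean, seed=stim.seed,
    )
    return trials, stim_out


def simulate_unbounded_ddm(
    params: DDMParams,
    stim: StimulusEnsemble,
    seed=None,
) -> pd.DataFrame:
    """Unbounded integration over a fixed-duration stimulus.

    The DV accumulates for the full stream; choice 1 if the terminal DV is
    positive, choice 2 if negative (exact ties broken at random).  The
    per-frame internal noise enters only through its sum, which is drawn in
    aggregate as N(0, n_frames * sigma_eta^2).
    """
    _, rng_eta, rng_misc = _rng_streams(seed, 3)
    n, F, dt = stim.n_trials, stim.n_frames, stim.frame_dt
    w = evaluate_weights(params.weight, stim.frame_times())
    dv = params.start_point + params.drift_offset * stim.duration
    dv = dv + stim.values.astype(np.float64) @ w
    if params.sigma_eta > 0:
        dv = dv + params.sigma_eta * np.sqrt(F) * rng_eta.standard_normal(n)
    tie = dv == 0
    sign = np.where(dv > 0, 1.0, -1.0)
    if tie.any():
        sign[tie] = rng_misc.choice([-1.0, 1.0], size=int(tie.sum()))
    decision_time = np.full(n, stim.duration)
    rt = decision_time.copy()
    if params.ndt is not None:
        rt = rt + sample_ndt(params.ndt, n, seed=rng_misc)
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "choice": np.where(sign > 0, 1, 2).astype(np.int64),
            "decision_time": decision_time,
            "rt": rt,
            "crossed": np.zeros(n, dtype=bool),
            "censored": np.zeros(n, dtype=bool),
            "terminal_dv": dv,
        }
    )
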