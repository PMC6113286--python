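"""Two competing accumulators with input correlation, leak, and inhibition.

Each choice has its own accumulator.  Per stimulus frame (the frame is the
unit of the dynamics' time constant, matching the per-frame noise units used
throughout the package) the pair of decision variables updates as

    v1 <- v1 + w_k s_k - L v1 - I v2 + v0 (L + I) + e1
    v2 <- v2 - w_k s_k - L v2 - I v1 + v0 (L + I) + e2

where the stimulus drives the two accumulators in opposite directions,
``L`` is the leak, ``I`` the mutual inhibition (both per frame), the
``v0 (L + I)`` term creates a stable point at the common starting value
``v0``, and ``(e1, e2)`` is bivariate Gaussian internal noise with per-frame
sd ``sigma_eta`` and correlation ``rho_prime``.  After every update both DVs
are clamped from below at the reflective bound ``R`` (a projection, modeling
the floor of neural firing rates); the first accumulator to reach the
absorbing bound ``B`` (optionally collapsing over time) sets the choice.

The *input* correlation rho -- the correlation of the accumulators' total
momentary inputs (stimulus drive plus internal noise) -- relates to the
noise correlation rho_prime through

    rho = (-w^2 sigma_s^2 + rho_prime sigma_eta^2) / (w^2 sigma_s^2 + sigma_eta^2).

With rho = -1, no leak/inhibition and no reflective bound, the difference
v1 - v2 performs a drift-diffusion walk and the model is equivalent to a DDM.
When leak and inhibition balance (L = I) the difference of DVs again
integrates evidence like a line attractor; imbalance creates point-attractor
(L > I) or saddle (L < I) dynamics with characteristic kernel distortions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddm import NDTSpec, UrgencySpec, _rng_streams, sample_ndt
from .stimgen import InvalidParameterError, StimulusEnsemble, WeightSpec, evaluate_weights

__all__ = ["RaceParams", "noise_correlation_for_target", "simulate_race"]

logger = logging.getLogger(__name__)


@dataclass
class RaceParams:
    """Full parameterization of the two-accumulator competition model."""

    rho_target: float = -1.0
    bound_B: float | None = None
    reflect_R: float = -np.inf
    leak_L: float = 0.0
    inhibition_I: float = 0.0
    v0: float = 0.0
    sigma_eta: float = 0.0
    weight: WeightSpec = field(default_factory=WeightSpec)
    ndt: NDTSpec | None = None
    urgency: UrgencySpec | None = None

    def __post_init__(self) -> None:
        if self.bound_B is None and self.urgency is None:
            raise InvalidParameterError("either bound_B or an urgency profile is required")
        if not -1.0 <= self.rho_target <= 0.0:
            raise InvalidParameterError("rho_target must lie in [-1, 0]")
        if self.leak_L < 0 or self.inhibition_I < 0:
            raise InvalidParameterError("leak_L and inhibition_I must be non-negative")
        if self.sigma_eta < 0:
            raise InvalidParameterError("sigma_eta must be non-negative")
        b0 = self.initial_bound
        if self.reflect_R >= b0:
            raise InvalidParameterError("reflect_R must be below the absorbing bound")
        if not (self.reflect_R <= self.v0 < b0):
            raise InvalidParameterError("v0 must lie in [reflect_R, bound_B)")
        if self.reflect_R < 0 and self.inhibition_I > 0:
            logger.warning(
                "reflect_R < 0 with inhibition_I > 0: negative DVs of one "
                "accumulator will excite the other; use reflect_R = 0 to prevent this"
            )

    @property
    def initial_bound(self) -> float:
        return self.urgency.b if self.urgency is not None else float(self.bound_B)

    @property
    def effective_bound(self) -> float:
        """Distance from the starting point to the absorbing bound.

        With anti-correlated inputs the difference of the two DVs behaves as
        a drift-diffusion walk whose bound equals this distance, so kernel
        normalization of the race model uses B - v0 rather than B itself.
        """
        return self.initial_bound - self.v0

    def bound_at(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if self.urgency is not None:
            from .ddm import bound_profile

            return np.asarray(bound_profile(times, self.urgency))
        return np.full(times.shape, float(self.bound_B))


def noise_correlation_for_target(
    rho_target: float,
    w: float = 1.0,
    sigma_s: float = 1.0,
    sigma_eta: float = 1.0,
) -> float | None:
    """Internal-noise correlation rho_prime that yields a desired input correlation.

    Returns None when ``sigma_eta == 0`` (the inputs are stimulus-only and
    perfectly anti-correlated; rho_prime is irrelevant).  Raises if the target
    is infeasible for the given variances, reporting the feasible range.
    """
    vs = (w * sigma_s) ** 2
    ve = sigma_eta**2
    if ve == 0.0:
        if not np.isclose(rho_target, -1.0):
            raise InvalidParameterError(
                "with sigma_eta = 0 the input correlation is exactly -1 (stimulus-only)"
            )
        return None
    rho_prime = (rho_target * (vs + ve) + vs) / ve
    if not -1.0 <= rho_prime <= 1.0:
        lo = -1.0
        hi = (ve - vs) / (ve + vs)
        raise InvalidParameterError(
            f"rho_target={rho_target} infeasible; feasible range is [{lo:.4f}, {hi:.4f}]"
        )
    return float(rho_prime)


def simulate_race(
    params: RaceParams,
    stim: StimulusEnsemble,
    seed=None,
    max_duration: float = 20.0,
    record_dv: bool = False,
) -> tuple[pd.DataFrame, StimulusEnsemble]:
    """Simulate the competition model on a stimulus ensemble (RT task).

    Undecided trials keep receiving fresh stimulus frames up to
    ``max_duration`` seconds, then are censored (``censored=True``) with a
    logged count.  When both accumulators cross in the same frame the choice
    is a fair coin flip; the number of such ties is logged and recorded in
    ``trials.attrs['n_ties']``.  Returns the outcome table and the (possibly
    extended) stimulus ensemble.
    """
    rng_stim, rng_eta, rng_misc = _rng_streams(seed, 3)
    n, dt = stim.n_trials, stim.frame_dt
    horizon = max(stim.n_frames, int(np.ceil(max_duration / dt - 1e-9)))

    if horizon > stim.n_frames:
        values = np.zeros((n, horizon), dtype=stim.values.dtype)
        values[:, : stim.n_frames] = stim.values
    else:
        values = stim.values

    w = evaluate_weights(params.weight, np.arange(horizon) * dt)
    bound = params.bound_at((np.arange(horizon) + 1) * dt)
    rho_prime = (
        noise_correlation_for_target(
            params.rho_target, w=float(w[0]), sigma_s=stim.sigma_s, sigma_eta=params.sigma_eta
        )
        if params.sigma_eta > 0
        else None
    )
    # Mixing coefficients for correlated bivariate noise.
    if rho_prime is not None:
        c1, c2 = rho_prime, float(np.sqrt(1.0 - rho_prime**2))

    L, I, v0 = params.leak_L, params.inhibition_I, params.v0
    stable = v0 * (L + I)
    R = params.reflect_R

    v1 = np.full(n, float(v0))
    v2 = np.full(n, float(v0))
    choice = np.zeros(n, dtype=np.int64)
    dec_frame = np.full(n, horizon - 1, dtype=np.int64)
    crossed = np.zeros(n, dtype=bool)
    active = np.arange(n)
    n_ties = 0
    dv_hist = np.full((n, horizon, 2), np.nan, dtype=np.float32) if record_dv else None

    for k in range(horizon):
        m = active.size
        if k >= stim.n_frames:
            s = rng_stim.standard_normal(m) * stim.sigma_s + stim.trial_mean[active]
            values[active, k] = s
        else:
            s = values[active, k].astype(np.float64)
        drive = w[k] * s
        a1, a2 = v1[active], v2[active]
        new1 = a1 + drive - L * a1 - I * a2 + stable
        new2 = a2 - drive - L * a2 - I * a1 + stable
        if params.sigma_eta > 0:
            z = rng_eta.standard_normal((2, m))
            new1 += params.sigma_eta * z[0]
            new2 += params.sigma_eta * (c1 * z[0] + c2 * z[1])
        if np.isfinite(R):
            np.maximum(new1, R, out=new1)
            np.maximum(new2, R, out=new2)
        v1[active], v2[active] = new1, new2
        if record_dv:
            dv_hist[active, k, 0] = new1
            dv_hist[active, k, 1] = new2
        hit1 = new1 >= bound[k]
        hit2 = new2 >= bound[k]
        anyhit = hit1 | hit2
        if anyhit.any():
            rows = np.nonzero(anyhit)[0]
            idx = active[rows]
            h1, h2 = hit1[rows], hit2[rows]
            ch = np.where(h1 & ~h2, 1, 2)
            both = h1 & h2
            if both.any():
                n_ties += int(both.sum())
                ch[both] = rng_misc.integers(1, 3, size=int(both.sum()))
            choice[idx] = ch
            dec_frame[idx] = k
            crossed[idx] = True
            active = active[~anyhit]
        if active.size == 0:
            break

    censored = np.zeros(n, dtype=bool)
    if active.size:
        censored[active] = True
        lead = v1[active] - v2[active]
        tie = lead == 0
        if tie.any():
            lead = lead.copy()
            lead[tie] = rng_misc.choice([-1.0, 1.0], size=int(tie.sum()))
        choice[active] = np.where(lead > 0, 1, 2)
        logger.warning(
            "%d of %d race trials did not cross within %.1f s and were censored",
            active.size, n, horizon * dt,
        )
    if n_ties:
        logger.info("%d race trials had both accumulators cross in one frame", n_ties)

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
            "terminal_dv": np.where(censored, v1 - v2, np.nan),
        }
    )
    trials.attrs["n_ties"] = n_ties
    if record_dv:
        trials.attrs["dv_history"] = dv_hist
    stim_out = stim if horizon == stim.n_frames else StimulusEnsemble(
        values=values, frame_dt=dt, sigma_s=stim.sigma_s,
        trial_mean=stim.trial_mean, seed=stim.seed,
    )
    return trials, stim_out
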