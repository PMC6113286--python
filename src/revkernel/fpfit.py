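"""Fokker-Planck likelihoods for bounded drift diffusion, and ML fitting.

The density p(v, t) of the decision variable obeys

    dp/dt = [ -d/dv mu + 0.5 d^2/dv^2 sigma_e^2 ] p(v, t),
    p(v, 0) = delta(v),   p(+-B, t) = 0,

with absorbing bounds at +-B.  The solver discretizes v on a uniform grid
and advances the probability *mass* per node with an implicit
(unconditionally stable) finite-difference step; the probability absorbed at
each bound per time step is computed from the discrete flux into the
boundary nodes, so that absorbed flux plus surviving mass is conserved to
machine precision.  Convolving the bound-crossing flux with the
non-decision-time density yields the predicted joint distribution of choices
and reaction times, whose log likelihood is maximized over
(B, sensitivity, T0, sigma_T0, and optionally temporal modulation terms
beta1, beta2) from multiple random starting points.

Drift parameterizations:

* ``coherence``: mu = gamma * C for stimulus strength C (the classic
  direction-discrimination setting; sigma_e = 1 absorbs all noise sources).
* ``time_varying``: mu(t) = gamma * C * (1 + beta1 t + beta2 t^2).
* ``multi_feature``: mu(t) = gamma_e s_e(t) + gamma_n s_n(t) + gamma_m s_m(t)
  using each trial's actual feature fluctuations (solved trial by trial);
  sigma_e = 1 is internal noise only.
* ``multi_feature_time_varying``: the above times (1 + beta1 t + beta2 t^2).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numba
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ddm import DDMParams, NDTSpec, _rng_streams
from .stimgen import (
    FaceFeatureStream,
    InvalidParameterError,
    StimulusEnsemble,
    WeightSpec,
)

__all__ = [
    "DriftSpec",
    "FPSolution",
    "FitResult",
    "SolverAccuracyError",
    "solve_fp",
    "rt_choice_likelihood",
    "choice_rt_densities",
    "fit_ml",
    "predict_kernels",
    "energy_to_coherence",
    "simulate_ddm_continuous",
    "simulate_coherence_trials",
    "frame_task_params",
    "frame_params_from_fit",
]

logger = logging.getLogger(__name__)

LIKELIHOOD_FLOOR = 1e-10
CONSERVATION_TOL = 1e-6


class SolverAccuracyError(RuntimeError):
    """Raised when the discretization cannot represent the problem accurately."""


@dataclass
class DriftSpec:
    """Drift-rate parameterization of the diffusion model."""

    mode: str = "coherence"
    gamma: float | None = None
    gamma_e: float | None = None
    gamma_n: float | None = None
    gamma_m: float | None = None
    beta1: float = 0.0
    beta2: float = 0.0
    sigma_e: float = 1.0

    def __post_init__(self) -> None:
        modes = ("coherence", "time_varying", "multi_feature", "multi_feature_time_varying")
        if self.mode not in modes:
            raise InvalidParameterError(f"unknown drift mode {self.mode!r}")
        if self.sigma_e <= 0:
            raise InvalidParameterError("sigma_e must be positive")
        if self.mode in ("coherence", "time_varying") and self.gamma is None:
            raise InvalidParameterError(f"mode {self.mode!r} requires gamma")
        if self.mode.startswith("multi_feature") and None in (
            self.gamma_e, self.gamma_n, self.gamma_m
        ):
            raise InvalidParameterError(f"mode {self.mode!r} requires gamma_e, gamma_n, gamma_m")

    @property
    def time_varying(self) -> bool:
        return self.mode in ("time_varying", "multi_feature_time_varying")

    def modulation(self, times: np.ndarray) -> np.ndarray:
        if self.time_varying:
            return 1.0 + self.beta1 * times + self.beta2 * times**2
        return np.ones_like(times)


@dataclass
class FPSolution:
    """Absorbed flux and surviving mass of the bounded diffusion over time.

    ``flux_upper[k]`` / ``flux_lower[k]`` are the probabilities absorbed at
    +B / -B during step k (the interval ``(times[k]-dt, times[k]]``);
    ``survivor_mass[k]`` is the probability still between the bounds at
    ``times[k]``.
    """

    times: np.ndarray
    flux_upper: np.ndarray
    flux_lower: np.ndarray
    survivor_mass: np.ndarray
    dt: float
    bound_B: float

    @property
    def p_upper(self) -> float:
        return float(self.flux_upper.sum())

    @property
    def p_lower(self) -> float:
        return float(self.flux_lower.sum())

    @property
    def conservation_error(self) -> float:
        return abs(self.p_upper + self.p_lower + float(self.survivor_mass[-1]) - 1.0)

    def mean_decision_time(self) -> float:
        flux = self.flux_upper + self.flux_lower
        return float(np.sum(self.times * flux) / np.sum(flux))


@numba.njit(cache=True)
def _fp_steps(q, mu, diff, dx, dt):  # pragma: no cover - compiled
    """Implicit-Euler steps of the mass vector q with per-step drift mu.

    Returns per-step absorbed flux at the upper and lower bound and the
    surviving mass.  Thomas-algorithm forward coefficients are recomputed
    only when the drift changes between steps.
    """
    n_steps = mu.size
    m = q.size
    flux_up = np.zeros(n_steps)
    flux_lo = np.zeros(n_steps)
    surv = np.zeros(n_steps)
    cp = np.empty(m)
    dp = np.empty(m)
    inv = np.empty(m)
    al = 0.0
    au = 0.0
    b = 1.0 + 2.0 * dt * diff / (dx * dx)
    prev = np.nan
    for k in range(n_steps):
        mk = mu[k]
        if mk != prev:
            al = dt * (diff / (dx * dx) + mk / (2.0 * dx))
            au = dt * (diff / (dx * dx) - mk / (2.0 * dx))
            inv[0] = 1.0 / b
            cp[0] = -au * inv[0]
            for i in range(1, m):
                inv[i] = 1.0 / (b + al * cp[i - 1])
                cp[i] = -au * inv[i]
            prev = mk
        dp[0] = q[0] * inv[0]
        for i in range(1, m):
            dp[i] = (q[i] + al * dp[i - 1]) * inv[i]
        total = dp[m - 1]
        q[m - 1] = dp[m - 1]
        for i in range(m - 2, -1, -1):
            q[i] = dp[i] - cp[i] * q[i + 1]
            total += q[i]
        # discrete boundary fluxes: advection with mu > 0 increases the flow
        # into the upper bound; these coefficients make absorbed flux plus
        # surviving mass conserve exactly
        flux_up[k] = al * q[m - 1]
        flux_lo[k] = au * q[0]
        surv[k] = total
    return flux_up, flux_lo, surv


def solve_fp(
    mu: float | np.ndarray,
    bound_B: float,
    sigma: float = 1.0,
    dt: float = 5e-4,
    n_grid: int = 513,
    horizon: float | None = None,
    frame_dt: float | None = None,
) -> FPSolution:
    """Solve the bounded Fokker-Planck problem from a delta start at 0.

    ``mu`` may be a constant drift or a per-frame series (with ``frame_dt``
    giving the frame duration; the drift is piecewise constant per frame).
    ``horizon`` is the solved duration in seconds (defaults to the length of
    the drift series).  Raises :class:`SolverAccuracyError` if probability
    is not conserved to within 1e-6 or the grid cannot resolve the drift.
    """
    if bound_B <= 0:
        raise InvalidParameterError("bound_B must be positive")
    if n_grid < 5 or n_grid % 2 == 0:
        raise InvalidParameterError("n_grid must be an odd integer >= 5")
    diff = 0.5 * sigma**2
    dx = 2.0 * bound_B / (n_grid - 1)
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    if mu_arr.size == 1:
        if horizon is None:
            raise InvalidParameterError("horizon is required for constant drift")
        n_steps = max(1, int(np.ceil(horizon / dt - 1e-9)))
        mu_steps = np.full(n_steps, float(mu_arr[0]))
    else:
        if frame_dt is None:
            raise InvalidParameterError("frame_dt is required for a drift series")
        if horizon is None:
            horizon = mu_arr.size * frame_dt
        n_steps = max(1, int(np.ceil(horizon / dt - 1e-9)))
        idx = np.minimum((np.arange(n_steps) * dt / frame_dt).astype(np.int64), mu_arr.size - 1)
        mu_steps = mu_arr[idx]
    peclet = np.max(np.abs(mu_steps)) * dx / (2.0 * diff)
    if peclet >= 1.0:
        raise SolverAccuracyError(
            f"cell Peclet number {peclet:.2f} >= 1; increase n_grid or reduce drift"
        )
    q = np.zeros(n_grid - 2)
    q[(n_grid - 2) // 2] = 1.0  # delta at v = 0 (center interior node)
    flux_up, flux_lo, surv = _fp_steps(q, mu_steps, diff, dx, dt)
    sol = FPSolution(
        times=(np.arange(n_steps) + 1) * dt,
        flux_upper=flux_up,
        flux_lower=flux_lo,
        survivor_mass=surv,
        dt=dt,
        bound_B=float(bound_B),
    )
    if sol.conservation_error > CONSERVATION_TOL:
        raise SolverAccuracyError(
            f"probability conservation error {sol.conservation_error:.2e} exceeds tolerance"
        )
    return sol


def _ndt_pmf(ndt: NDTSpec, dt: float) -> np.ndarray:
    """Non-decision-time probability mass on the solver's time bins."""
    if ndt.sd_T0 == 0.0:
        k = int(round(ndt.mean_T0 / dt))
        pmf = np.zeros(k + 1)
        pmf[k] = 1.0
        return pmf
    n = int(np.ceil((ndt.mean_T0 + 6.0 * ndt.sd_T0) / dt)) + 1
    edges = np.arange(n + 1) * dt
    if ndt.family == "gaussian":
        a = -ndt.mean_T0 / ndt.sd_T0
        cdf = stats.truncnorm.cdf(edges, a, np.inf, loc=ndt.mean_T0, scale=ndt.sd_T0)
    else:
        shape = (ndt.mean_T0 / ndt.sd_T0) ** 2
        scale = ndt.sd_T0**2 / ndt.mean_T0
        cdf = stats.gamma.cdf(edges, shape, scale=scale)
    pmf = np.diff(cdf)
    s = pmf.sum()
    if s <= 0:
        raise InvalidParameterError("degenerate non-decision time distribution")
    return pmf / s


def choice_rt_densities(fp: FPSolution, ndt: NDTSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RT densities (per second) for each choice on an extended time grid.

    Convolves the bound-crossing flux with the non-decision-time mass at the
    solver resolution.  Returns (times, density_upper, density_lower).
    """
    from scipy.signal import fftconvolve

    pmf = _ndt_pmf(ndt, fp.dt)
    dens_up = np.maximum(fftconvolve(fp.flux_upper, pmf), 0.0) / fp.dt
    dens_lo = np.maximum(fftconvolve(fp.flux_lower, pmf), 0.0) / fp.dt
    times = (np.arange(dens_up.size) + 1) * fp.dt
    return times, dens_up, dens_lo


def rt_choice_likelihood(
    fp: FPSolution, ndt: NDTSpec, rt: np.ndarray, choice: np.ndarray
) -> np.ndarray:
    """Per-trial log densities of (choice, RT) under a solved model.

    RTs beyond the solved horizon (plus the non-decision-time support) fall
    to the likelihood floor with a warning.
    """
    rt = np.atleast_1d(np.asarray(rt, dtype=float))
    choice = np.atleast_1d(np.asarray(choice))
    _, dens_up, dens_lo = choice_rt_densities(fp, ndt)
    idx = np.ceil(rt / fp.dt - 1e-9).astype(np.int64) - 1
    beyond = idx >= dens_up.size
    if beyond.any():
        logger.warning("%d RTs beyond the solver horizon; likelihood floored", int(beyond.sum()))
    idx = np.clip(idx, 0, dens_up.size - 1)
    dens = np.where(choice == 1, dens_up[idx], dens_lo[idx])
    dens = np.where(beyond, 0.0, dens)
    return np.log(np.maximum(dens, LIKELIHOOD_FLOOR))


@dataclass
class FitResult:
    """Maximum-likelihood fit of the bounded diffusion to choices and RTs."""

    params: dict
    loglik: float
    n_restarts: int
    converged: bool
    mode: str
    restarts: list = field(default_factory=list)
    se: dict | None = None
    solver: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls(**json.load(fh))


_PARAM_BOXES = {
    # log-uniform randomized starting boxes for the optimizer restarts
    "B": (0.6, 2.5),
    "gamma": (4.0, 35.0),
    "T0": (0.15, 0.5),
    "sigma_T0": (0.03, 0.2),
}


def _fit_param_names(mode: str, fit_betas: bool) -> list[str]:
    if mode.startswith("multi_feature"):
        names = ["B", "gamma_e", "gamma_n", "gamma_m", "T0", "sigma_T0"]
    else:
        names = ["B", "gamma", "T0", "sigma_T0"]
    if fit_betas:
        names += ["beta1", "beta2"]
    return names


def _pack(params: dict, names: list[str]) -> np.ndarray:
    x = []
    for nm in names:
        v = params[nm]
        x.append(np.log(v) if nm in ("B", "T0", "sigma_T0") else v)
    return np.array(x)


def _unpack(x: np.ndarray, names: list[str]) -> dict:
    out = {}
    for nm, v in zip(names, x):
        out[nm] = float(np.exp(v)) if nm in ("B", "T0", "sigma_T0") else float(v)
    return out


def _coherence_negloglik(params, trials_by_cond, horizon, mode, solver):
    from scipy.signal import fftconvolve

    ndt = NDTSpec(mean_T0=params["T0"], sd_T0=params["sigma_T0"], family="gaussian")
    dt = solver["dt"]
    pmf = _ndt_pmf(ndt, dt)
    total = 0.0
    for cond, (rt, choice) in trials_by_cond.items():
        # each condition is solved only up to its own longest RT
        h = float(rt.max()) + dt
        if mode == "time_varying":
            # modulation quantized to ~25 ms segments: the drift changes slowly,
            # and piecewise-constant segments let the solver reuse factorizations
            n_steps = int(np.ceil(h / dt))
            seg = max(1, int(round(0.025 / dt)))
            n_seg = -(-n_steps // seg)
            t = (np.arange(n_seg) + 0.5) * seg * dt
            mu_seg = params["gamma"] * cond * (
                1.0 + params.get("beta1", 0.0) * t + params.get("beta2", 0.0) * t**2
            )
            mu = np.repeat(mu_seg, seg)[:n_steps]
            fp = solve_fp(mu, params["B"], dt=dt, n_grid=solver["n_grid"],
                          horizon=h, frame_dt=dt)
        else:
            fp = solve_fp(params["gamma"] * cond, params["B"], dt=dt,
                          n_grid=solver["n_grid"], horizon=h)
        dens_up = np.maximum(fftconvolve(fp.flux_upper, pmf), 0.0) / dt
        dens_lo = np.maximum(fftconvolve(fp.flux_lower, pmf), 0.0) / dt
        idx = np.clip(np.ceil(rt / dt - 1e-9).astype(np.int64) - 1, 0, dens_up.size - 1)
        dens = np.where(choice == 1, dens_up[idx], dens_lo[idx])
        total += np.log(np.maximum(dens, LIKELIHOOD_FLOOR)).sum()
    return -total


def _multifeature_negloglik(params, rt, choice, features, frame_dt, mode, solver):
    ndt = NDTSpec(mean_T0=params["T0"], sd_T0=params["sigma_T0"], family="gaussian")
    pmf = _ndt_pmf(ndt, solver["dt"])
    gam = np.array([params["gamma_e"], params["gamma_n"], params["gamma_m"]])
    total = 0.0
    for i in range(rt.size):
        mu_frames = features[i] @ gam
        if mode == "multi_feature_time_varying":
            t = (np.arange(mu_frames.size) + 0.5) * frame_dt
            mu_frames = mu_frames * (1.0 + params.get("beta1", 0.0) * t
                                     + params.get("beta2", 0.0) * t**2)
        fp = solve_fp(mu_frames, params["B"], dt=solver["dt"], n_grid=solver["n_grid"],
                      horizon=rt[i] + solver["dt"], frame_dt=frame_dt)
        flux = fp.flux_upper if choice[i] == 1 else fp.flux_lower
        j = min(int(np.ceil(rt[i] / solver["dt"] - 1e-9)) - 1, flux.size - 1)
        lo = max(0, j - pmf.size + 1)
        dens = float(flux[lo : j + 1] @ pmf[j - np.arange(lo, j + 1)]) / solver["dt"]
        total += np.log(max(dens, LIKELIHOOD_FLOOR))
    return -total


def fit_ml(
    trials: pd.DataFrame,
    mode: str = "coherence",
    features: np.ndarray | None = None,
    frame_dt: float | None = None,
    n_restarts: int = 10,
    seed=None,
    dt: float = 2e-3,
    n_grid: int = 129,
    maxiter: int = 500,
    compute_se: bool = True,
) -> FitResult:
    """Fit the bounded diffusion to a choice/RT table by maximum likelihood.

    ``trials`` needs columns ``choice`` (1/2), ``rt`` (seconds), and
    ``coherence`` (signed stimulus strength; coherence modes), or a
    ``features`` array (n_trials x n_frames x 3 per-frame evidence, morph
    fractions) with ``frame_dt`` for the multi-feature modes.  The optimizer
    is a derivative-free simplex restarted from ``n_restarts`` randomized
    starting points (log-uniform in the documented boxes); the best restart
    is returned, with standard errors from the numerical Hessian.
    """
    fit_betas = mode in ("time_varying", "multi_feature_time_varying")
    names = _fit_param_names(mode, fit_betas)
    solver = {"dt": dt, "n_grid": n_grid}
    rt = trials["rt"].to_numpy(dtype=float)
    choice = trials["choice"].to_numpy()
    if np.any(rt <= 0):
        raise InvalidParameterError("RTs must be positive")
    horizon = float(rt.max()) + dt

    if mode in ("coherence", "time_varying"):
        if "coherence" not in trials.columns:
            raise InvalidParameterError("coherence modes require a 'coherence' column")
        coh = trials["coherence"].to_numpy(dtype=float)
        trials_by_cond = {
            c: (rt[coh == c], choice[coh == c]) for c in np.unique(coh)
        }

        def nll_of(params):
            return _coherence_negloglik(params, trials_by_cond, horizon, mode, solver)

    else:
        if features is None or frame_dt is None:
            raise InvalidParameterError("multi-feature modes require features and frame_dt")

        def nll_of(params):
            return _multifeature_negloglik(params, rt, choice, features, frame_dt, mode, solver)

    def objective(x):
        params = _unpack(x, names)
        try:
            return nll_of(params)
        except (SolverAccuracyError, InvalidParameterError):
            return 1e12

    rng = np.random.default_rng(seed)
    restarts = []
    best = None
    for r in range(n_restarts):
        start = {}
        for nm in names:
            if nm in ("beta1", "beta2"):
                start[nm] = rng.normal(0.0, 0.3)
            else:
                box = _PARAM_BOXES["gamma" if nm.startswith("gamma") else nm]
                start[nm] = np.exp(rng.uniform(np.log(box[0]), np.log(box[1])))
        res = optimize.minimize(
            objective, _pack(start, names), method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 2e-2},
        )
        restarts.append({"start": start, "loglik": -float(res.fun), "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("optimizer failed to converge from any restart")

    params = _unpack(best.x, names)
    se = None
    if compute_se:
        se = _hessian_se(nll_of, params, names)
    logger.info("fit_ml(%s): loglik=%.2f params=%s", mode, -best.fun, params)
    return FitResult(
        params=params,
        loglik=-float(best.fun),
        n_restarts=n_restarts,
        converged=any(r["success"] for r in restarts),
        mode=mode,
        restarts=restarts,
        se=se,
        solver=solver,
    )


def _hessian_se(nll_of, params: dict, names: list[str], rel_step: float = 1e-2) -> dict:
    """Standard errors from the finite-difference Hessian of the negative loglik."""
    p0 = np.array([params[nm] for nm in names])
    steps = np.maximum(np.abs(p0) * rel_step, 1e-4)

    def f(p):
        return nll_of({nm: v for nm, v in zip(names, p)})

    k = len(p0)
    H = np.zeros((k, k))
    f0 = f(p0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                H[i, i] = (f(p0 + ei) - 2 * f0 + f(p0 - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(p0 + ei + ej) - f(p0 + ei - ej) - f(p0 - ei + ej) + f(p0 - ei - ej)
                ) / (4 * steps[i] * steps[j])
    try:
        cov = np.linalg.pinv(H)
        diag = np.clip(np.diag(cov), 0.0, None)
        return {nm: float(np.sqrt(d)) for nm, d in zip(names, diag)}
    except np.linalg.LinAlgError:  # pragma: no cover
        return {nm: np.nan for nm in names}


def frame_task_params(
    gamma: float,
    B: float,
    T0: float,
    sigma_T0: float,
    sigma_s: float,
    frame_dt: float,
    sigma_e: float = 1.0,
    beta1: float = 0.0,
    beta2: float = 0.0,
) -> DDMParams:
    """Translate continuous-time diffusion parameters to frame-simulator units.

    The sensitivity gamma (per second per unit stimulus) becomes a per-frame
    weight gamma * frame_dt applied to the stimulus values; the per-frame
    internal noise makes up the remainder of the total momentary-evidence
    variance sigma_e^2 * frame_dt after the stimulus fluctuations (sd
    sigma_s per frame) are accounted for.
    """
    var_eta = sigma_e**2 * frame_dt - (gamma * frame_dt * sigma_s) ** 2
    if var_eta < 0:
        raise InvalidParameterError(
            "stimulus fluctuations alone exceed the total evidence variance"
        )
    if beta1 != 0.0 or beta2 != 0.0:
        weight = WeightSpec(kind="polynomial", gamma=gamma * frame_dt,
                            beta1=beta1, beta2=beta2)
    else:
        weight = WeightSpec(kind="constant", gamma=gamma * frame_dt)
    return DDMParams(
        bound_B=B,
        sigma_eta=float(np.sqrt(var_eta)),
        ndt=NDTSpec(mean_T0=T0, sd_T0=sigma_T0),
        weight=weight,
    )


def frame_params_from_fit(
    fit: FitResult, sigma_s: float, frame_dt: float, sigma_e: float = 1.0
) -> DDMParams:
    """Frame-resolution simulator parameters corresponding to a fit."""
    p = fit.params
    if p.get("gamma") is None:
        raise InvalidParameterError("frame translation requires a single-sensitivity fit")
    betas = (
        {"beta1": p.get("beta1", 0.0), "beta2": p.get("beta2", 0.0)}
        if fit.mode == "time_varying"
        else {}
    )
    return frame_task_params(
        p["gamma"], p["B"], p["T0"], p["sigma_T0"], sigma_s, frame_dt,
        sigma_e=sigma_e, **betas,
    )


def predict_kernels(
    fit: FitResult,
    stim: StimulusEnsemble | FaceFeatureStream,
    seed=None,
    max_duration: float = 20.0,
):
    """Predict psychophysical kernels from a fit on fresh neutral streams.

    Forwards the fitted parameters into the frame-resolution simulator on the
    supplied mean-zero stimulus ensemble, then estimates stimulus- and
    response-aligned kernels windowed at the simulated median RT.  Returns a
    dict with keys ``trials``, ``stimulus``, ``response``, ``median_rt``.
    """
    from .ddm import simulate_bounded_ddm
    from .revcorr import compute_kernel

    if isinstance(stim, FaceFeatureStream):
        p = fit.params
        gam = np.array([p["gamma_e"], p["gamma_n"], p["gamma_m"]])
        drive = (stim.values @ gam) * stim.frame_dt
        mod = np.ones(stim.n_frames)
        if fit.mode == "multi_feature_time_varying":
            t = stim.frame_times()
            mod = 1.0 + p.get("beta1", 0.0) * t + p.get("beta2", 0.0) * t**2
        ens = StimulusEnsemble(
            values=drive * mod[None, :], frame_dt=stim.frame_dt,
            sigma_s=0.0, trial_mean=np.zeros(stim.n_trials),
        )
        params = DDMParams(
            bound_B=p["B"],
            sigma_eta=float(np.sqrt(stim.frame_dt)),  # sigma_e^2 = 1, internal only
            ndt=NDTSpec(mean_T0=p["T0"], sd_T0=p["sigma_T0"]),
            weight=WeightSpec(kind="constant", gamma=1.0),
        )
        trials, _ = simulate_bounded_ddm(params, ens, seed=seed, max_duration=max_duration)
        median_rt = float(np.median(trials["rt"]))
        return {
            "trials": trials,
            "stimulus": compute_kernel(stim, trials, "stimulus", window=median_rt),
            "response": compute_kernel(stim, trials, "response", window=median_rt),
            "median_rt": median_rt,
        }

    params = frame_params_from_fit(fit, stim.sigma_s, stim.frame_dt)
    trials, stim_full = simulate_bounded_ddm(params, stim, seed=seed, max_duration=max_duration)
    median_rt = float(np.median(trials["rt"]))
    return {
        "trials": trials,
        "stimulus": compute_kernel(stim_full, trials, "stimulus", window=median_rt),
        "response": compute_kernel(stim_full, trials, "response", window=median_rt),
        "median_rt": median_rt,
    }


def energy_to_coherence(energies: np.ndarray, slope: float) -> np.ndarray:
    """Convert motion energies to coherence equivalents via the calibration slope."""
    if slope <= 0:
        raise InvalidParameterError("calibration slope must be positive")
    return np.asarray(energies, dtype=float) / slope


def simulate_ddm_continuous(
    mu: float | np.ndarray,
    bound_B: float,
    sigma: float = 1.0,
    n_trials: int = 1000,
    dt: float = 1e-3,
    horizon: float = 10.0,
    ndt: NDTSpec | None = None,
    seed=None,
    bridge: bool = True,
    block_steps: int = 512,
    start: float = 0.0,
) -> pd.DataFrame:
    """Monte-Carlo first-passage simulation of the continuous diffusion.

    Euler steps of size ``dt`` with (by default) a Brownian-bridge crossing
    correction between consecutive steps, which removes the O(sqrt(dt))
    first-passage bias of naive Euler.  ``mu`` may be constant or a per-step
    series.  Used as the independent stochastic oracle for the
    Fokker-Planck solution and to generate synthetic choice/RT datasets.
    """
    rng_w, rng_b, rng_misc = _rng_streams(seed, 3)
    n_steps = int(np.ceil(horizon / dt))
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    if mu_arr.size == 1:
        mu_arr = np.full(n_steps, float(mu_arr[0]))
    elif mu_arr.size < n_steps:
        mu_arr = np.concatenate([mu_arr, np.full(n_steps - mu_arr.size, mu_arr[-1])])
    if abs(start) >= bound_B:
        raise InvalidParameterError("|start| must be smaller than the bound")
    sdt = sigma * np.sqrt(dt)

    dv = np.full(n_trials, float(start))
    choice = np.zeros(n_trials, dtype=np.int64)
    dec_step = np.full(n_trials, n_steps - 1, dtype=np.int64)
    crossed = np.zeros(n_trials, dtype=bool)
    active = np.arange(n_trials)

    for s0 in range(0, n_steps, block_steps):
        s1 = min(s0 + block_steps, n_steps)
        nb = s1 - s0
        inc = sdt * rng_w.standard_normal((active.size, nb)) + mu_arr[s0:s1] * dt
        np.cumsum(inc, axis=1, out=inc)
        path = inc + dv[active, None]
        up = path >= bound_B
        lo = path <= -bound_B
        hit = up | lo
        if bridge:
            prev = np.concatenate([dv[active, None], path[:, :-1]], axis=1)
            interior = ~hit
            with np.errstate(over="ignore"):
                p_up = np.exp(-2.0 * (bound_B - prev) * (bound_B - path) / (sigma**2 * dt))
                p_lo = np.exp(-2.0 * (bound_B + prev) * (bound_B + path) / (sigma**2 * dt))
            u = rng_b.random(path.shape)
            b_up = interior & (u < p_up)
            b_lo = interior & ~b_up & (u < p_up + p_lo)
            up = up | b_up
            lo = lo | b_lo
            hit = up | lo
        anyhit = hit.any(axis=1)
        rows = np.nonzero(anyhit)[0]
        if rows.size:
            first = np.argmax(hit[rows], axis=1)
            idx = active[rows]
            choice[idx] = np.where(up[rows, first], 1, 2)
            dec_step[idx] = s0 + first
            crossed[idx] = True
        surv = ~anyhit
        dv[active[surv]] = path[surv, -1]
        active = active[surv]
        if active.size == 0:
            break

    censored = np.zeros(n_trials, dtype=bool)
    if active.size:
        censored[active] = True
        choice[active] = np.where(dv[active] > 0, 1, 2)
        logger.warning("%d continuous-DDM trials censored at horizon", active.size)
    decision_time = (dec_step + 1) * dt
    rt = decision_time.astype(float)
    if ndt is not None:
        from .ddm import sample_ndt

        rt = rt + sample_ndt(ndt, n_trials, seed=rng_misc)
    return pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "choice": choice,
            "decision_time": decision_time,
            "rt": rt,
            "crossed": crossed,
            "censored": censored,
            "terminal_dv": np.where(censored, dv, np.nan),
        }
    )


def simulate_coherence_trials(
    gamma: float,
    bound_B: float,
    T0: float,
    sigma_T0: float,
    coherences,
    n_trials: int,
    seed=None,
    beta1: float = 0.0,
    beta2: float = 0.0,
    dt: float = 1e-3,
    horizon: float = 10.0,
) -> pd.DataFrame:
    """Synthetic choice/RT dataset for the coherence task (sigma_e = 1).

    Trials are split evenly over the coherence levels; drift for level C is
    gamma * C * (1 + beta1 t + beta2 t^2).  Returns a trial table with a
    ``coherence`` column, ready for :func:`fit_ml`.
    """
    ss = np.random.SeedSequence(seed)
    coherences = np.asarray(coherences, dtype=float)
    per = np.full(len(coherences), n_trials // len(coherences))
    per[: n_trials - per.sum()] += 1
    ndt = NDTSpec(mean_T0=T0, sd_T0=sigma_T0)
    out = []
    for c, m, child in zip(coherences, per, ss.spawn(len(coherences))):
        t = (np.arange(int(np.ceil(horizon / dt))) + 0.5) * dt
        mu = gamma * c * (1.0 + beta1 * t + beta2 * t**2)
        df = simulate_ddm_continuous(
            mu, bound_B, n_trials=int(m), dt=dt, horizon=horizon, ndt=ndt, seed=child
        )
        df["coherence"] = c
        out.append(df)
    trials = pd.concat(out, ignore_index=True)
    trials["trial_id"] = np.arange(len(trials))
    return trials
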