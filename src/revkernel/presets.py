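"""End-to-end pipeline and named presets for the canonical simulation regimes.

Each preset bundles the generative model, stimulus statistics, and analysis
conventions of one regime explored in the package's validation suite:

* ``unbounded-constant`` -- unbounded integration of a fixed 1-s stimulus
  with a constant unit weight; the normalized kernel recovers the weight.
* ``bounded-basic`` -- bounded accumulation (B = 30 per-frame units, unit
  stimulus and internal noise) without non-decision time; kernels are flat
  at the weight after the 2 sigma_s^2 / B normalization.
* ``bounded-ndt`` -- adds a Gaussian non-decision time (300 +- 100 ms); the
  bound (B = 10) puts decision times on the scale of human reaction times so
  the characteristic kernel distortions are prominent.
* ``urgency`` -- hyperbolically collapsing bound (b = 60, u_inf = 60,
  tau_half = 0.4 s): kernels inflate over time.
* ``race-correlation`` -- two accumulators with input correlation -0.2
  (B = 30, no leak/inhibition, unit internal noise).
* ``race-reflective`` -- anti-correlated accumulators with a reflective
  floor at -10 (B = 30, no internal noise).
* ``race-leak-inhibition`` -- leak + inhibition = 0.006 per frame with a
  configurable ratio (B = 60, reflective floor 0, start 30).
* ``mixed-opposing`` -- a competition model combining collapsing bounds,
  non-decision time, partial input correlation, leak and inhibition, whose
  opposing kernel distortions can cancel.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
from scipy import stats as sps

from . import __version__
from .ddm import DDMParams, NDTSpec, UrgencySpec, simulate_bounded_ddm, simulate_unbounded_ddm
from .io import ExperimentConfig, config_hash, weightspec_from_dict, write_kernel, write_trials
from .race import RaceParams, simulate_race
from .revcorr import compute_kernel, normalize_kernel, sigma_tot_discrete
from .stimgen import FRAME_DT_DOTS, InvalidParameterError, generate_gaussian_stimulus

__all__ = ["PRESETS", "get_preset", "run_pipeline", "kernel_shape_report"]

logger = logging.getLogger(__name__)


def _cfg(name, model, n_trials=100_000, n_frames=75, frame_dt=FRAME_DT_DOTS, **analysis):
    return ExperimentConfig(
        name=name,
        model=model,
        stimulus={
            "n_trials": n_trials,
            "n_frames": n_frames,
            "frame_dt": frame_dt,
            "sigma_s": 1.0,
            "trial_means": 0.0,
        },
        analysis={"alignments": ["stimulus", "response"], "normalization": "auto", **analysis},
    )


PRESETS = {
    "unbounded-constant": lambda: _cfg(
        "unbounded-constant", {"kind": "unbounded", "sigma_eta": 1.0},
        alignments=["stimulus"],
    ),
    "bounded-basic": lambda: _cfg(
        "bounded-basic", {"kind": "ddm", "bound_B": 30.0, "sigma_eta": 1.0,
                          "max_duration": 40.0},
    ),
    "bounded-ndt": lambda: _cfg(
        "bounded-ndt",
        {"kind": "ddm", "bound_B": 10.0, "sigma_eta": 1.0,
         "ndt": {"mean_T0": 0.3, "sd_T0": 0.1}},
    ),
    "urgency": lambda: _cfg(
        "urgency",
        {"kind": "ddm", "sigma_eta": 1.0,
         "urgency": {"b": 60.0, "u_inf": 60.0, "tau_half": 0.4}},
    ),
    "race-correlation": lambda: _cfg(
        "race-correlation",
        {"kind": "race", "rho_target": -0.2, "bound_B": 30.0, "sigma_eta": 1.0,
         "v0": 0.0, "max_duration": 40.0},
    ),
    "race-reflective": lambda: _cfg(
        "race-reflective",
        {"kind": "race", "rho_target": -1.0, "bound_B": 30.0, "reflect_R": -10.0,
         "sigma_eta": 0.0, "v0": 0.0, "max_duration": 40.0},
    ),
    "race-leak-inhibition": lambda: _cfg(
        "race-leak-inhibition",
        {"kind": "race", "rho_target": -1.0, "bound_B": 60.0, "reflect_R": 0.0,
         "leak_L": 0.003, "inhibition_I": 0.003, "sigma_eta": 0.0, "v0": 30.0,
         "max_duration": 60.0},
    ),
    "mixed-opposing": lambda: _cfg(
        "mixed-opposing",
        {"kind": "race", "rho_target": -0.5, "bound_B": None, "reflect_R": 0.0,
         "leak_L": 0.003, "inhibition_I": 0.003, "sigma_eta": 1.0, "v0": 30.0,
         "urgency": {"b": 60.0, "u_inf": 60.0, "tau_half": 0.4},
         "ndt": {"mean_T0": 0.3, "sd_T0": 0.1}, "max_duration": 40.0},
    ),
}


def get_preset(name: str, n_trials: int | None = None, seed: int = 0) -> ExperimentConfig:
    if name not in PRESETS:
        raise InvalidParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    cfg = PRESETS[name]()
    if n_trials is not None:
        cfg.stimulus["n_trials"] = int(n_trials)
    cfg.seed = int(seed)
    return cfg


def _build_model(model: dict):
    kw = {k: v for k, v in model.items() if k not in ("kind", "max_duration")}
    if "weight" in kw:
        kw["weight"] = weightspec_from_dict(kw["weight"])
    if kw.get("ndt") is not None:
        kw["ndt"] = NDTSpec(**kw["ndt"])
    if kw.get("urgency") is not None:
        kw["urgency"] = UrgencySpec(**kw["urgency"])
    if model["kind"] == "race":
        return RaceParams(**kw)
    if model["kind"] == "unbounded" and kw.get("bound_B") is None and kw.get("urgency") is None:
        kw["bound_B"] = np.inf  # no absorbing bound in the unbounded model
    return DDMParams(**kw)


def kernel_shape_report(kernel) -> dict:
    """Simple monotonicity/shape diagnostics of a kernel estimate."""
    ok = np.isfinite(kernel.values)
    t = kernel.times[ok]
    v = kernel.values[ok]
    rho, p = sps.spearmanr(t, v)
    report = {"spearman_rho": float(rho), "spearman_p": float(p)}
    if kernel.alignment == "response":
        peak = int(np.nanargmax(kernel.values))
        final = len(kernel.values) - 1
        report["peak_time"] = float(kernel.times[peak])
        report["final_bin_z"] = float(kernel.values[final] / kernel.sem[final])
        report["peak_minus_final_se"] = float(
            (kernel.values[peak] - kernel.values[final])
            / np.sqrt(kernel.sem[peak] ** 2 + kernel.sem[final] ** 2)
        )
    return report


def run_pipeline(config: ExperimentConfig, outdir) -> dict:
    """Run simulate -> kernel (-> report) with a single seed; write artifacts.

    Writes the trial table, raw and normalized kernels per requested
    alignment, and a machine-readable manifest (package version, seed,
    config and its hash, stage timings, shape diagnostics).  Returns the
    manifest as a dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings = {}
    t0 = time.perf_counter()
    stim = generate_gaussian_stimulus(
        n_trials=int(config.stimulus["n_trials"]),
        n_frames=int(config.stimulus.get("n_frames", 75)),
        frame_dt=float(config.stimulus.get("frame_dt", FRAME_DT_DOTS)),
        sigma_s=float(config.stimulus.get("sigma_s", 1.0)),
        trial_means=config.stimulus.get("trial_means", 0.0),
        seed=np.random.SeedSequence(config.seed).spawn(1)[0],
        dtype=np.float32,
    )
    timings["stimulus"] = time.perf_counter() - t0

    model = _build_model(config.model)
    sim_seed = np.random.SeedSequence(config.seed).spawn(2)[1]
    kind = config.model["kind"]
    t0 = time.perf_counter()
    if kind == "unbounded":
        trials = simulate_unbounded_ddm(model, stim, seed=sim_seed)
        stim_full = stim
    elif kind == "ddm":
        trials, stim_full = simulate_bounded_ddm(
            model, stim, seed=sim_seed,
            max_duration=float(config.model.get("max_duration", 20.0)),
        )
    else:
        trials, stim_full = simulate_race(
            model, stim, seed=sim_seed,
            max_duration=float(config.model.get("max_duration", 20.0)),
        )
    timings["simulate"] = time.perf_counter() - t0

    write_trials(outdir / "trials.csv", trials)

    alignments = config.analysis.get("alignments", ["stimulus"])
    normalization = config.analysis.get("normalization", "auto")
    window = config.analysis.get("window")
    shape_reports = {}
    t0 = time.perf_counter()
    for alignment in alignments:
        kernel = compute_kernel(
            stim_full, trials, alignment=alignment, window=window,
            inclusion=config.analysis.get("inclusion", "onset"),
        )
        write_kernel(outdir / f"kernel_{alignment}_raw.csv", kernel)
        if normalization != "raw":
            if kind == "unbounded":
                sig_tot = sigma_tot_discrete(
                    stim.n_frames, config.model.get("sigma_eta", 0.0), stim.sigma_s
                )
                kernel_n = normalize_kernel(kernel, sigma_s=stim.sigma_s, sigma_tot=sig_tot)
            elif getattr(model, "urgency", None) is not None:
                from .revcorr import mean_bound_height

                b_eff = mean_bound_height(
                    model.urgency, float(np.median(trials["rt"]))
                ) - getattr(model, "v0", 0.0)
                kernel_n = normalize_kernel(kernel, sigma_s=stim.sigma_s, bound=b_eff)
            else:
                bound = getattr(model, "effective_bound", model.initial_bound)
                kernel_n = normalize_kernel(kernel, sigma_s=stim.sigma_s, bound=bound)
            write_kernel(outdir / f"kernel_{alignment}_normalized.csv", kernel_n)
            shape_reports[alignment] = kernel_shape_report(kernel_n)
    timings["kernels"] = time.perf_counter() - t0

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "timings": timings,
        "n_censored": int(trials["censored"].sum()),
        "shape_reports": shape_reports,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    logger.info("pipeline %s: wrote artifacts to %s", config.name, outdir)
    return manifest
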