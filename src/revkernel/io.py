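"""Trial-table, stimulus, kernel, and configuration I/O.

Formats: CSV for trial tables and kernels (with a JSON sidecar carrying
kernel metadata), HDF5 for stimulus ensembles and trial tables, YAML for
experiment configurations.  Reaction times are always stored in seconds and
choices as integers 1/2.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .ddm import TRIAL_COLUMNS
from .revcorr import KernelEstimate
from .stimgen import InvalidParameterError, StimulusEnsemble, WeightSpec

__all__ = [
    "read_trials",
    "write_trials",
    "write_stimulus",
    "read_stimulus",
    "write_kernel",
    "read_kernel",
    "weightspec_to_dict",
    "weightspec_from_dict",
    "ExperimentConfig",
    "load_config",
    "save_config",
    "config_hash",
]

_REQUIRED_TRIAL_COLUMNS = ["trial_id", "choice", "rt"]


def _validate_trials(table: pd.DataFrame) -> pd.DataFrame:
    for col in _REQUIRED_TRIAL_COLUMNS:
        if col not in table.columns:
            raise InvalidParameterError(f"trial table is missing required column {col!r}")
    if not np.isin(table["choice"].to_numpy(), [1, 2]).all():
        raise InvalidParameterError("column 'choice' must contain only 1 or 2")
    if (table["rt"].to_numpy(dtype=float) < 0).any():
        raise InvalidParameterError("column 'rt' contains negative reaction times")
    return table


def write_trials(path, table: pd.DataFrame) -> None:
    """Write a trial table to CSV or HDF5 (by extension)."""
    _validate_trials(table)
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            for col in table.columns:
                fh.create_dataset(col, data=table[col].to_numpy())
    else:
        table.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            table = pd.DataFrame({k: fh[k][...] for k in fh.keys()})
        order = [c for c in TRIAL_COLUMNS if c in table.columns]
        order += [c for c in table.columns if c not in order]
        table = table[order]
    else:
        table = pd.read_csv(path)
    return _validate_trials(table)


def write_stimulus(path, stim: StimulusEnsemble) -> None:
    """Write a stimulus ensemble (HDF5, or CSV with one frame column per frame)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=stim.values)
            fh.create_dataset("trial_mean", data=stim.trial_mean)
            fh.attrs["frame_dt"] = stim.frame_dt
            fh.attrs["sigma_s"] = stim.sigma_s
            if stim.seed is not None:
                fh.attrs["seed"] = stim.seed
    else:
        df = pd.DataFrame(stim.values, columns=[f"f{k:04d}" for k in range(stim.n_frames)])
        df.insert(0, "condition", stim.trial_mean)
        df.insert(0, "trial_id", np.arange(stim.n_trials))
        df.to_csv(path, index=False)
        meta = {"frame_dt": stim.frame_dt, "sigma_s": stim.sigma_s, "seed": stim.seed}
        path.with_suffix(".json").write_text(json.dumps(meta))


def read_stimulus(path) -> StimulusEnsemble:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            return StimulusEnsemble(
                values=fh["values"][...],
                trial_mean=fh["trial_mean"][...],
                frame_dt=float(fh.attrs["frame_dt"]),
                sigma_s=float(fh.attrs["sigma_s"]),
                seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
            )
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    frame_cols = [c for c in df.columns if c.startswith("f")]
    return StimulusEnsemble(
        values=df[frame_cols].to_numpy(),
        trial_mean=df["condition"].to_numpy(),
        frame_dt=float(meta["frame_dt"]),
        sigma_s=float(meta["sigma_s"]),
        seed=meta.get("seed"),
    )


def write_kernel(path, kernel: KernelEstimate) -> None:
    """Write a kernel as CSV plus a JSON sidecar with its metadata."""
    path = Path(path)
    kernel.to_frame().to_csv(path, index=False)
    meta = {
        "alignment": kernel.alignment,
        "normalization": kernel.normalization,
        "scale_value": kernel.scale_value,
        "window_end": kernel.window_end,
        "frame_dt": kernel.frame_dt,
        "feature": kernel.feature,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=float))


def read_kernel(path) -> KernelEstimate:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return KernelEstimate(
        times=df["time"].to_numpy(),
        values=df["value"].to_numpy(),
        sem=df["sem"].to_numpy(),
        n_contributing=df["n"].to_numpy(),
        alignment=meta["alignment"],
        frame_dt=meta["frame_dt"],
        normalization=meta["normalization"],
        scale_value=meta["scale_value"],
        window_end=meta["window_end"],
        feature=meta.get("feature"),
    )


def weightspec_to_dict(spec: WeightSpec) -> dict:
    return dataclasses.asdict(spec)


def weightspec_from_dict(d: dict) -> WeightSpec:
    allowed = {f.name for f in dataclasses.fields(WeightSpec)}
    unknown = set(d) - allowed
    if unknown:
        raise InvalidParameterError(f"unknown WeightSpec keys: {sorted(unknown)}")
    return WeightSpec(**d)


_MODEL_KEYS = {
    "kind", "bound_B", "sigma_eta", "start_point", "drift_offset", "weight", "ndt",
    "urgency", "rho_target", "reflect_R", "leak_L", "inhibition_I", "v0", "max_duration",
}
_STIM_KEYS = {"n_trials", "n_frames", "frame_dt", "sigma_s", "trial_means"}
_ANALYSIS_KEYS = {"alignments", "normalization", "window", "inclusion"}


@dataclasses.dataclass
class ExperimentConfig:
    """Validated configuration of a simulate -> kernel pipeline run.

    ``model.kind`` is one of ``ddm``, ``unbounded``, ``race``; the remaining
    model keys mirror the parameter fields of the corresponding simulator.
    Unknown keys anywhere are rejected.
    """

    model: dict
    stimulus: dict
    analysis: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    name: str = "experiment"

    def __post_init__(self) -> None:
        unknown = set(self.model) - _MODEL_KEYS
        if unknown:
            raise InvalidParameterError(f"unknown model keys: {sorted(unknown)}")
        unknown = set(self.stimulus) - _STIM_KEYS
        if unknown:
            raise InvalidParameterError(f"unknown stimulus keys: {sorted(unknown)}")
        unknown = set(self.analysis) - _ANALYSIS_KEYS
        if unknown:
            raise InvalidParameterError(f"unknown analysis keys: {sorted(unknown)}")
        if self.model.get("kind") not in ("ddm", "unbounded", "race"):
            raise InvalidParameterError("model.kind must be one of ddm, unbounded, race")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    allowed = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise InvalidParameterError(f"unknown config sections: {sorted(unknown)}")
    return ExperimentConfig(**raw)


def save_config(path, config: ExperimentConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
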