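"""Serialization: trial tables as CSV, epochs as HDF5, fits as JSON,
configs as YAML.  All containers carry a schema version and fail loudly
on mismatch or truncation rather than returning partial data."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, EpochSet
from .ddm import QuantileFit, SubjectParams
from .mediation import MediationResult

SCHEMA_VERSION = "1"

__all__ = ["write_trials_csv", "read_trials_csv", "write_epochs_h5",
           "read_epochs_h5", "write_fit_json", "read_fit_json",
           "write_mediation_json", "load_cohort_config", "dump_cohort_config",
           "SCHEMA_VERSION"]

_BOOL_COLS = ("is_error", "detected")


def _np_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_trials_csv(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in _BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_epochs_h5(epochs: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["alignment"] = epochs.alignment
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("trial_index", data=np.asarray(epochs.trial_index))
        f.create_dataset("channels",
                         data=np.array(epochs.channels, dtype="S"))


def read_epochs_h5(path: str | Path) -> EpochSet:
    try:
        with h5py.File(path, "r") as f:
            version = f.attrs.get("schema_version")
            if version != SCHEMA_VERSION:
                raise ValueError(
                    f"epoch container schema {version!r} != {SCHEMA_VERSION!r}")
            return EpochSet(
                data=f["data"][()],
                times=f["times"][()],
                channels=tuple(c.decode() for c in f["channels"][()]),
                alignment=str(f.attrs["alignment"]),
                sampling_rate=float(f.attrs["sampling_rate"]),
                trial_index=f["trial_index"][()],
            )
    except OSError as err:
        raise ValueError(f"unreadable epoch container {path}: {err}") from err


def write_fit_json(fit: QuantileFit, path: str | Path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **fit.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_np_default))


def read_fit_json(path: str | Path) -> QuantileFit:
    payload = json.loads(Path(path).read_text())
    if payload.pop("schema_version", None) != SCHEMA_VERSION:
        raise ValueError("fit JSON schema mismatch")
    params = SubjectParams(**payload.pop("params"))
    for k in ("quantiles", "O", "E"):
        payload[k] = np.asarray(payload[k])
    return QuantileFit(params=params, **payload)


def write_mediation_json(result: MediationResult, path: str | Path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **result.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_np_default))


def dump_cohort_config(config: CohortConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


def load_cohort_config(path: str | Path) -> CohortConfig:
    raw = yaml.safe_load(Path(path).read_text())
    for key in ("ddm_mean", "ddm_sd", "deadline_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return CohortConfig(**raw)
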