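"""CSV/JSON round-tripping for trajectories, dose logs and configs.

Schemas (all CSV, header required):

* trajectory:  ``t_min, sbp, mbp, dbp, valid``  (``valid`` in {0, 1};
  pressure fields may be empty/NaN on invalid rows)
* action log:  ``t_min, bolus_mg, rate_mg_h, rate_ml_h, mode, note``
* drug record: ``t_min, bolus_mg, rate_mg_h`` (one row per epoch)

Times are minutes from evaluation start.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .controller import (
    ControllerConfig,
    DoseAction,
    InvalidInputError,
    NIBPReading,
    RatePolicy,
)

TRAJECTORY_COLUMNS = ["t_min", "sbp", "mbp", "dbp", "valid"]
ACTION_COLUMNS = ["t_min", "bolus_mg", "rate_mg_h", "rate_ml_h", "mode", "note"]
DRUG_COLUMNS = ["t_min", "bolus_mg", "rate_mg_h"]


def write_trajectory(path: str | Path, readings: Sequence[NIBPReading]) -> None:
    df = pd.DataFrame({
        "t_min": [r.t for r in readings],
        "sbp": [r.sbp if r.valid else math.nan for r in readings],
        "mbp": [r.mbp if r.valid else math.nan for r in readings],
        "dbp": [r.dbp if r.valid else math.nan for r in readings],
        "valid": [int(r.valid) for r in readings],
    })
    df.to_csv(path, index=False, float_format="%.4f")


def read_trajectory(path: str | Path) -> list[NIBPReading]:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    readings = []
    for i, row in enumerate(df.itertuples(index=False)):
        valid = bool(int(row.valid))
        try:
            readings.append(NIBPReading(
                t=float(row.t_min),
                sbp=float(row.sbp) if valid else math.nan,
                mbp=float(row.mbp) if valid else math.nan,
                dbp=float(row.dbp) if valid else math.nan,
                valid=valid,
            ))
        except (InvalidInputError, ValueError) as exc:
            raise InvalidInputError(f"{path}: row {i + 2}: {exc}") from exc
    return readings


def write_actions(path: str | Path, actions: Sequence[DoseAction],
                  config: ControllerConfig) -> None:
    df = pd.DataFrame({
        "t_min": [a.t for a in actions],
        "bolus_mg": [a.bolus for a in actions],
        "rate_mg_h": [a.rate_setpoint for a in actions],
        "rate_ml_h": [a.rate_setpoint / config.conc for a in actions],
        "mode": ["VASOPRESSOR" if a.note not in ("none", "exit") else "NORMAL"
                 for a in actions],
        "note": [a.note for a in actions],
    })
    df.to_csv(path, index=False, float_format="%.4f")


def write_drug_record(path: str | Path, times: Sequence[float],
                      boluses: Sequence[float], rates: Sequence[float]) -> None:
    pd.DataFrame({"t_min": times, "bolus_mg": boluses, "rate_mg_h": rates}) \
        .to_csv(path, index=False, float_format="%.4f")


def _policy_from_dict(d: dict) -> RatePolicy:
    return RatePolicy(**d)


def load_controller_config(path: str | Path) -> ControllerConfig:
    """Read a ControllerConfig from a JSON document mirroring its fields."""
    with open(path) as fh:
        raw = json.load(fh)
    if "rate_policy" in raw and isinstance(raw["rate_policy"], dict):
        raw["rate_policy"] = _policy_from_dict(raw["rate_policy"])
    try:
        return ControllerConfig(**raw)
    except TypeError as exc:
        raise InvalidInputError(f"{path}: {exc}") from exc


def dump_controller_config(config: ControllerConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def save_json(path: str | Path, obj: object) -> None:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if hasattr(o, "tolist"):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")


def load_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
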