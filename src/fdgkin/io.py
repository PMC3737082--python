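"""CSV curve formats, run configuration, and result serialization.

Curve files are plain CSV (comma, UTF-8, header row):

* sampled curves (blood or plasma): ``time_s,activity_kBq_cm3``
* frame TACs: ``start_s,end_s,activity_kBq_cm3``

Units are fixed by the headers.  Results and fixture manifests are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .curves import FrameTAC, SampledCurve

__all__ = [
    "read_curve",
    "write_curve",
    "RunConfig",
    "load_config",
    "dump_json",
    "file_digest",
]

CURVE_COLUMNS = ["time_s", "activity_kBq_cm3"]
TAC_COLUMNS = ["start_s", "end_s", "activity_kBq_cm3"]


class CurveParseError(ValueError):
    """CSV did not validate as a curve; message names the offending row."""


def read_curve(path, kind: str = "plasma") -> SampledCurve | FrameTAC:
    """Read a curve CSV.  ``kind`` is ``"blood"``, ``"plasma"`` or ``"tac"``.

    Row numbers in error messages are 1-based data rows (excluding the
    header).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    want = TAC_COLUMNS if kind == "tac" else CURVE_COLUMNS
    missing = [c for c in want if c not in df.columns]
    if missing:
        raise CurveParseError(f"{path}: missing column(s) {missing}; expected header {want}")
    if kind == "tac":
        start = df["start_s"].to_numpy(float)
        end = df["end_s"].to_numpy(float)
        bad = np.nonzero(end <= start)[0]
        if bad.size:
            raise CurveParseError(
                f"{path}: row {bad[0] + 1}: frame end ({end[bad[0]]}) must exceed "
                f"start ({start[bad[0]]})"
            )
        if start.size > 1:
            gap = np.nonzero(~np.isclose(end[:-1], start[1:]))[0]
            if gap.size:
                raise CurveParseError(
                    f"{path}: row {gap[0] + 2}: frames not contiguous "
                    f"(previous end {end[gap[0]]}, start {start[gap[0] + 1]})"
                )
        return FrameTAC(start, end, df["activity_kBq_cm3"].to_numpy(float))
    times = df["time_s"].to_numpy(float)
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        raise CurveParseError(
            f"{path}: row {bad[0] + 2}: time_s not strictly increasing "
            f"({times[bad[0]]} -> {times[bad[0] + 1]})"
        )
    try:
        return SampledCurve(times, df["activity_kBq_cm3"].to_numpy(float), kind=kind)
    except ValueError as e:
        raise CurveParseError(f"{path}: {e}") from e


def write_curve(curve: SampledCurve | FrameTAC, path) -> Path:
    """Write a curve to CSV with the documented header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(curve, FrameTAC):
        df = pd.DataFrame(
            {"start_s": curve.start, "end_s": curve.end, "activity_kBq_cm3": curve.values}
        )
    else:
        df = pd.DataFrame({"time_s": curve.times, "activity_kBq_cm3": curve.values})
    df.to_csv(path, index=False)
    return path


class FitOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    vb: Union[float, Literal["free"]] = 0.055
    fit_k4: bool = True
    weights: Optional[Literal["duration"]] = None

    @field_validator("vb")
    @classmethod
    def _vb_range(cls, v):
        if isinstance(v, float) and not (0.0 <= v <= 1.0):
            raise ValueError("fixed vb must lie in [0, 1]")
        return v


class ProtocolOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    duration: float = 300.0
    scan_length: float = 2700.0


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    if_path: Optional[str] = None
    blood_path: Optional[str] = None
    tac_path: Optional[str] = None
    protocol: ProtocolOptions = ProtocolOptions()
    correction: Literal["mouse_exp", "rat_biexp", "constant_scale", "whole_blood"] = "mouse_exp"
    fit: FitOptions = FitOptions()
    studies: list[
        Literal["vb", "shift", "calibration", "smoothing", "blood-correction", "protocol", "tradeoff"]
    ] = []
    seed: int = 0

    def digest(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def dump_json(data: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(data), indent=2, sort_keys=True) + "\n")
    return path


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]
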