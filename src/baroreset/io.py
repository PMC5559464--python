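"""Delimited-text series I/O and structured-text parameter files.

Series travel as comma-separated text with header ``time,pressure,sna``
and an optional ``label`` column; parameter objects (logistic parameters,
circuit constants, modulatory sets) travel as JSON keyed by field name.
Round-trips are lossless to well beyond 10 significant digits (floats are
written with ``repr`` precision).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .circuit import CircuitParams, ModulatorySet
from .logistic import LogisticParams, PressureSnaSeries

__all__ = [
    "read_series",
    "write_series",
    "read_params",
    "write_params",
]

ParamObject = Union[LogisticParams, CircuitParams, ModulatorySet]

_KIND_TO_CLASS: dict[str, type] = {
    "logistic": LogisticParams,
    "circuit": CircuitParams,
    "modulatory": ModulatorySet,
}


def read_series(path: str | Path) -> PressureSnaSeries:
    """Read a ``time,pressure,sna[,label]`` CSV into a series.

    Malformed headers or non-numeric fields raise ``ValueError`` naming
    the offending column or line.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["time", "pressure", "sna"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: header must contain columns time,pressure,sna[,label]; "
            f"missing {', '.join(missing)}"
        )
    for col in required:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header row, one for 1-based line numbers
            line = int(bad.idxmax()) + 2
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
        if numeric.isna().any():
            line = int(numeric.isna().idxmax()) + 2
            raise ValueError(f"{path}: missing value in column {col!r} at line {line}")
        df[col] = numeric

    label = None
    if "label" in df.columns:
        labels = df["label"].dropna().unique()
        if len(labels) > 1:
            raise ValueError(f"{path}: multiple labels in one series: {list(labels)}")
        label = str(labels[0]) if len(labels) else None

    return PressureSnaSeries(
        pressure=df["pressure"].to_numpy(float),
        sna=df["sna"].to_numpy(float),
        time=df["time"].to_numpy(float),
        label=label,
    )


def write_series(series: PressureSnaSeries, path: str | Path) -> None:
    """Write a series as ``time,pressure,sna[,label]`` CSV."""
    path = Path(path)
    n = len(series)
    time = series.time if series.time is not None else np.arange(n, dtype=float)
    data = {"time": time, "pressure": series.pressure, "sna": series.sna}
    if series.label is not None:
        data["label"] = [series.label] * n
    # float_format=None keeps full repr precision for lossless round-trips
    pd.DataFrame(data).to_csv(path, index=False)


def _param_kind(obj: ParamObject) -> str:
    for kind, cls in _KIND_TO_CLASS.items():
        if isinstance(obj, cls):
            return kind
    raise TypeError(f"unsupported parameter object {type(obj).__name__}")


def write_params(obj: ParamObject, path: str | Path) -> None:
    """Serialize a parameter object as JSON with a ``kind`` tag."""
    payload = {"kind": _param_kind(obj)}
    payload.update(dataclasses.asdict(obj))
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_params(path: str | Path) -> ParamObject:
    """Read a parameter JSON file back into its dataclass.

    Unknown keys are rejected and missing required keys are named, so a
    typo in a config fails loudly rather than silently using a default.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: expected a JSON object of parameter keys")

    payload = dict(payload)
    kind = payload.pop("kind", None)
    if kind is None:
        # infer from the key set for untagged files
        keys = set(payload)
        if keys == {"a1", "a2", "a3", "a4"}:
            kind = "logistic"
        elif keys <= {"m1", "m2", "m3", "m4"} and keys:
            kind = "modulatory"
        else:
            kind = "circuit"
    cls = _KIND_TO_CLASS.get(kind)
    if cls is None:
        raise ValueError(
            f"{path}: unknown parameter kind {kind!r}; "
            f"expected one of {sorted(_KIND_TO_CLASS)}"
        )

    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - fields
    if unknown:
        raise ValueError(
            f"{path}: unknown key(s) for {cls.__name__}: {', '.join(sorted(unknown))}"
        )
    required = {
        f.name
        for f in dataclasses.fields(cls)
        if f.default is dataclasses.MISSING
        and f.default_factory is dataclasses.MISSING  # type: ignore[misc]
    }
    missing = required - set(payload)
    if missing:
        raise ValueError(
            f"{path}: missing required key(s) for {cls.__name__}: "
            f"{', '.join(sorted(missing))}"
        )
    return cls(**payload)
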