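"""File I/O: JSON parameter blobs and CSV tables.

Conventions: JSON for parameter sets and summaries; CSV (comma-separated,
mandatory header, '.' decimal, UTF-8) for curves, datasets and
trajectories.  Temperature columns carry their unit in the header —
``temperature_K`` or ``temperature_C`` — and Celsius input is converted on
read with T_K = T_C + 273.15.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .vft import MemoryPoint

__all__ = [
    "MalformedInputError",
    "CELSIUS_OFFSET",
    "read_json",
    "write_json",
    "read_memory_csv",
    "write_memory_csv",
]

CELSIUS_OFFSET = 273.15


class MalformedInputError(ValueError):
    """An input file that cannot be parsed into the expected shape."""


def read_json(path: str | Path) -> dict:
    try:
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise MalformedInputError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(obj, dict):
        raise MalformedInputError(f"{path}: expected a JSON object at top level")
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _temperature_kelvin(df: pd.DataFrame, path) -> pd.Series:
    if "temperature_K" in df.columns:
        return df["temperature_K"].astype(float)
    if "temperature_C" in df.columns:
        return df["temperature_C"].astype(float) + CELSIUS_OFFSET
    raise MalformedInputError(
        f"{path}: need a 'temperature_K' or 'temperature_C' column, got {list(df.columns)}"
    )


def read_memory_csv(path: str | Path) -> list[MemoryPoint]:
    """Read labelled holding observations (temperature, time_min, label)."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise MalformedInputError(f"{path}: {exc}") from exc
    temps = _temperature_kelvin(df, path)
    if "time_min" not in df.columns or "label" not in df.columns:
        raise MalformedInputError(
            f"{path}: need columns 'time_min' and 'label', got {list(df.columns)}"
        )
    points = []
    for idx, (T, t, lab) in enumerate(zip(temps, df["time_min"], df["label"])):
        try:
            points.append(MemoryPoint(T=float(T), holding_time=float(t), label=str(lab)))
        except (ValueError, TypeError) as exc:
            raise MalformedInputError(f"{path}: row {idx + 2}: {exc}") from exc
    return points


def write_memory_csv(points: list[MemoryPoint], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.T, p.holding_time, p.label) for p in points],
        columns=["temperature_K", "time_min", "label"],
    )
    df.to_csv(path, index=False)
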