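"""Delimited-table and structured-document I/O.

Barrier and rate series travel as headered delimited text with columns
``temperature_K`` (or ``temperature_C``, auto-converted), ``value`` and
optionally ``sem``.  Configurations and reports are YAML documents.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .thermokinetics import BarrierSeries, RateSeries

CELSIUS_OFFSET = 273.15

Series = Union[BarrierSeries, RateSeries]


class SeriesFormatError(ValueError):
    """Malformed series table."""


def _find_column(df: pd.DataFrame, names) -> str | None:
    lower = {c.lower().strip(): c for c in df.columns}
    for n in names:
        if n in lower:
            return lower[n]
    return None


def read_series(path, kind: str = "barrier") -> Series:
    """Read a barrier or rate series from headered delimited text.

    Accepts comma-, tab- or whitespace-delimited files.  A
    ``temperature_C`` column is converted to kelvin.  Unsorted rows are
    sorted with a warning; non-numeric cells raise an error naming the
    offending line.
    """
    if kind not in ("barrier", "rate"):
        raise ValueError(f"unknown series kind {kind!r}")
    df = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)
    t_col = _find_column(df, ["temperature_k", "temperature"])
    celsius = False
    if t_col is None:
        t_col = _find_column(df, ["temperature_c"])
        celsius = t_col is not None
    v_col = _find_column(df, ["value", "dg", "k", "rate", "barrier"])
    if t_col is None or v_col is None:
        raise SeriesFormatError(
            f"{path}: required columns missing (need temperature_K/"
            f"temperature_C and value; found {list(df.columns)})"
        )
    s_col = _find_column(df, ["sem", "se", "stderr"])

    def numeric(col):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header line, one for 0- vs 1-based counting
            raise SeriesFormatError(
                f"{path}: non-numeric value {df[col][bad[0]]!r} in column "
                f"{col!r} at line {bad[0] + 2}"
            )
        if vals.isna().any():
            raise SeriesFormatError(
                f"{path}: empty cell in column {col!r} at line "
                f"{int(vals.index[vals.isna()][0]) + 2}"
            )
        return vals.to_numpy(float)

    T = numeric(t_col)
    if celsius:
        T = T + CELSIUS_OFFSET
    value = numeric(v_col)
    sem = numeric(s_col) if s_col is not None else None

    if np.any(np.diff(T) <= 0):
        warnings.warn(f"{path}: temperatures not sorted; sorting", stacklevel=2)
        order = np.argsort(T)
        T = T[order]
        value = value[order]
        if sem is not None:
            sem = sem[order]
    if kind == "barrier":
        return BarrierSeries(T, value, sem)
    return RateSeries(T, value, sem)


def write_series(path, series: Series) -> None:
    """Write a series as comma-delimited text with a header."""
    path = Path(path)
    value = series.dG if isinstance(series, BarrierSeries) else series.k
    cols = {"temperature_K": series.T, "value": value}
    if series.sem is not None and np.any(np.asarray(series.sem) > 0):
        cols["sem"] = series.sem
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


def series_to_text(series: Series) -> str:
    """The exact text `write_series` would produce (determinism checks)."""
    buf = _io.StringIO()
    value = series.dG if isinstance(series, BarrierSeries) else series.k
    cols = {"temperature_K": series.T, "value": value}
    if series.sem is not None and np.any(np.asarray(series.sem) > 0):
        cols["sem"] = series.sem
    pd.DataFrame(cols).to_csv(buf, index=False, float_format="%.10g")
    return buf.getvalue()


def read_config(path) -> dict:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def write_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(path, report: dict) -> None:
    """Serialize a pipeline report as YAML (machine-readable)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(report), fh, sort_keys=False)


def report_to_text(report: dict) -> str:
    return yaml.safe_dump(_jsonable(report), sort_keys=False)
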