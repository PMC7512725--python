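"""Reading signals from text files and writing results as CSV/TSV."""

from __future__ import annotations

import os
from typing import Any

import numpy as np
import pandas as pd

from .baselines import MaybeEntropy
from .core import EntropyResult

__all__ = ["read_signal", "write_result", "UNDEFINED_TOKEN"]

#: Serialization token for undefined (e.g. SampEn) values.
UNDEFINED_TOKEN = "undefined"


def read_signal(path: str | os.PathLike, column: int | str = 0) -> np.ndarray:
    """Read a univariate signal from a single- or multi-column text file.

    Accepts plain text or CSV, one sample per row, with an optional header
    line.  ``column`` selects by 0-based index or by header name.
    Non-numeric or missing entries are rejected with their line number.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    rows = [(i + 1, ln) for i, ln in enumerate(lines) if ln]
    if not rows:
        raise ValueError(f"empty input file: {path}")

    sep = "," if "," in rows[0][1] else None
    header: list[str] | None = None
    first_fields = [f.strip() for f in rows[0][1].split(sep)]
    if not all(_is_number(f) for f in first_fields):
        header = first_fields
        rows = rows[1:]
        if not rows:
            raise ValueError(f"no data rows in {path}")
    col = _col_index(column, header)

    values = np.empty(len(rows))
    for k, (lineno, ln) in enumerate(rows):
        fields = ln.split(sep)
        if col >= len(fields):
            raise ValueError(f"{path}:{lineno}: missing column {column}")
        token = fields[col].strip()
        try:
            v = float(token)
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: non-numeric value {token!r}"
            ) from None
        if not np.isfinite(v):
            raise ValueError(f"{path}:{lineno}: non-finite value {token!r}")
        values[k] = v
    return values


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _col_index(column: int | str, header: list[str] | None) -> int:
    if isinstance(column, int):
        return column
    if header is None:
        raise ValueError(f"column name {column!r} given but file has no header")
    try:
        return header.index(column)
    except ValueError:
        raise ValueError(f"column {column!r} not found in header {header}") from None


def _fmt(v: Any) -> Any:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return UNDEFINED_TOKEN
    if isinstance(v, float):
        return float(f"{v:.6g}")
    return v


def write_result(
    result: EntropyResult | MaybeEntropy | pd.DataFrame,
    path: str | os.PathLike,
    fmt: str = "csv",
) -> None:
    """Write an entropy result or experiment table to CSV/TSV.

    Floats are serialized at 6 significant digits; undefined values as the
    token ``undefined``, never as a number.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(fmt)
    if sep is None:
        raise ValueError(f"format must be 'csv' or 'tsv', got {fmt!r}")
    if isinstance(result, pd.DataFrame):
        df = result.copy()
        for col in df.columns:
            if df[col].dtype == object or df[col].dtype.kind == "f":
                df[col] = df[col].map(_fmt)
        df.to_csv(path, sep=sep, index=False)
        return
    if isinstance(result, MaybeEntropy):
        df = pd.DataFrame(
            [{"estimator": "sampen", "value": _fmt(result.value), "reason": result.reason or ""}]
        )
        df.to_csv(path, sep=sep, index=False)
        return
    p = result.params
    df = pd.DataFrame(
        [
            {
                "estimator": "fdispen" if p.flavor == "fluctuation" else "dispen",
                "mapping": str(getattr(p.mapping, "value", p.mapping)),
                "m": p.m,
                "c": p.c,
                "d": p.d,
                "value": _fmt(result.raw),
                "normalized": _fmt(result.normalized),
                "observed_patterns": result.observed_patterns,
                "forbidden_patterns": result.forbidden_patterns,
            }
        ]
    )
    df.to_csv(path, sep=sep, index=False)
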