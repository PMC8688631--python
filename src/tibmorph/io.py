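"""CSV readers/writers, plain-text config, seed fan-out and atomic writes.

All CSVs are UTF-8 with '.' decimal separators.  Report-style tables are
written at 2-decimal mm precision; intermediate contour files keep full
precision so pipelines round-trip bit-identically.
"""

from __future__ import annotations

import os
import tempfile
import zlib
from typing import Callable

import numpy as np
import pandas as pd

from .errors import TibmorphError
from .mesh_resection import PlanarContour
from .morphometry import PARAMETER_NAMES

__all__ = [
    "atomic_write_text",
    "derive_seed",
    "write_contour_csv",
    "read_contour_csv",
    "write_records_csv",
    "read_records_csv",
    "write_size_table_csv",
    "read_size_table_csv",
    "write_wss_csv",
    "read_config",
]

CONTOUR_HEADER = ["point_index", "x_mm", "y_mm"]
RECORD_COLUMNS = ["subject_id", "gender", "side", *PARAMETER_NAMES]


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write a text file atomically (temp file + rename in the same dir)."""
    path = os.fspath(path)
    directory = os.path.dirname(os.path.abspath(path))
    os.makedirs(directory, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp", text=True)
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def derive_seed(master_seed: int, stage: str) -> int:
    """Fan one top-level seed out to an independent, reproducible stage seed."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def write_contour_csv(path, contour: PlanarContour) -> None:
    lines = [",".join(CONTOUR_HEADER)]
    for i, (x, y) in enumerate(contour.points):
        lines.append(f"{i},{float(x)!r},{float(y)!r}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_contour_csv(path) -> PlanarContour:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CONTOUR_HEADER if c not in df.columns]
    if missing:
        raise TibmorphError(f"{path}: contour CSV missing columns {missing}")
    df = df.sort_values("point_index", kind="stable")
    return PlanarContour(points=df[["x_mm", "y_mm"]].to_numpy(dtype=float))


def _write_df(path, df: pd.DataFrame, float_format: str | None) -> None:
    atomic_write_text(path, df.to_csv(index=False, float_format=float_format))


def write_records_csv(path, records: pd.DataFrame, precision: int = 2) -> None:
    """Morphometric record table; measured floats printed to 0.01 mm."""
    cols = [c for c in RECORD_COLUMNS if c in records.columns]
    cols += [c for c in records.columns if c not in cols]
    _write_df(path, records[cols], f"%.{precision}f")


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PARAMETER_NAMES if c not in df.columns]
    if missing:
        raise TibmorphError(f"{path}: record CSV missing columns {missing}")
    return df


def write_size_table_csv(path, table: pd.DataFrame) -> None:
    _write_df(path, table[["size", "gender", "ap_mm", "ml_mm"]], "%.2f")


def read_size_table_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("size", "gender", "ap_mm", "ml_mm")
               if c not in df.columns]
    if missing:
        raise TibmorphError(f"{path}: size-table CSV missing columns {missing}")
    return df


def write_wss_csv(path, curve) -> None:
    df = pd.DataFrame({"k": curve.k_values, "wss": curve.wss_values})
    _write_df(path, df, "%.6f")


def read_config(path) -> dict[str, str]:
    """Plain-text ``key = value`` config; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise TibmorphError(f"{path}:{lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
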