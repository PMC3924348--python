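"""ESRI ASCII grid and CSV table input/output.

Grids use the plain-text ESRI ASCII raster format (``ncols``/``nrows``
header, optional ``NODATA_value``, whitespace-separated cell rows, row 0
at the top). Cell size is nominal metadata only — no projection handling.
Tables go through :mod:`pandas` CSV with a header row.
"""

from __future__ import annotations

import os
from typing import Any

import numpy as np
import pandas as pd

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


class GridFormatError(ValueError):
    """Malformed ESRI ASCII grid."""


def write_grid(
    path: str | os.PathLike,
    grid: np.ndarray,
    *,
    cellsize: float = 30.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: float | int | None = None,
) -> None:
    """Write a 2-D array as an ESRI ASCII grid.

    NaN cells are emitted as the nodata sentinel (default ``-9999`` when the
    array contains NaN and no sentinel was given).
    """
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise GridFormatError(f"grid must be 2-D, got shape {grid.shape}")
    has_nan = np.issubdtype(grid.dtype, np.floating) and bool(np.isnan(grid).any())
    if nodata is None and has_nan:
        nodata = -9999
    lines = [
        f"ncols {grid.shape[1]}",
        f"nrows {grid.shape[0]}",
        f"xllcorner {xllcorner}",
        f"yllcorner {yllcorner}",
        f"cellsize {cellsize}",
    ]
    if nodata is not None:
        lines.append(f"NODATA_value {nodata}")
    out = grid
    if has_nan:
        out = np.where(np.isnan(grid), nodata, grid)
    if np.issubdtype(grid.dtype, np.integer):
        body = "\n".join(" ".join(str(int(v)) for v in row) for row in out)
    else:
        body = "\n".join(" ".join(repr(float(v)) for v in row) for row in out)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n" + body + "\n")


def read_grid(path: str | os.PathLike, *, dtype: Any = float) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid.

    Returns ``(grid, header)``. For float dtypes, nodata cells come back as
    NaN; for integer dtypes they keep the sentinel (recorded in the header).
    """
    header: dict[str, float] = {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not rows and key in _HEADER_KEYS:
                if len(parts) != 2:
                    raise GridFormatError(f"{path}:{lineno}: malformed header line {raw!r}")
                header[key] = float(parts[1])
            else:
                rows.append(parts)
    if "ncols" not in header or "nrows" not in header:
        raise GridFormatError(f"{path}: missing ncols/nrows header")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    flat = [v for row in rows for v in row]
    if len(flat) != nrows * ncols:
        raise GridFormatError(
            f"{path}: expected {nrows * ncols} cells ({nrows}x{ncols}), found {len(flat)}"
        )
    try:
        grid = np.array(flat, dtype=float).reshape(nrows, ncols)
    except ValueError as exc:
        raise GridFormatError(f"{path}: non-numeric cell value ({exc})") from exc
    nodata = header.get("nodata_value")
    if np.issubdtype(np.dtype(dtype), np.floating):
        if nodata is not None:
            grid = np.where(grid == nodata, np.nan, grid)
        return grid.astype(dtype), header
    return grid.astype(dtype), header


def write_table(path: str | os.PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(
    path: str | os.PathLike, *, columns: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Read a CSV table; if *columns* is given, reorder/validate by header name."""
    df = pd.read_csv(path)
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        df = df[list(columns)]
    return df
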