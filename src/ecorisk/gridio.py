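"""Grid and table I/O.

Grids are written as ESRI ASCII-grid (text, ``.asc``) or single-band TIFF
(``.tif``/``.tiff``, via tifffile; no georeferencing tags). Nodata cells are
NaN in memory and the sentinel -9999 on disk. Tables are CSV with a header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

NODATA = -9999.0


class GridFormatError(ValueError):
    pass


def write_ascii_grid(
    grid: np.ndarray,
    path,
    cellsize_km: float = 1.0,
    nodata: float = NODATA,
) -> None:
    arr = np.asarray(grid, dtype=float)
    if arr.ndim != 2:
        raise GridFormatError("ASCII grid writer expects a 2-D array")
    out = np.where(np.isnan(arr), nodata, arr)
    rows, cols = arr.shape
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner 0.0\n"
        f"yllcorner 0.0\n"
        f"cellsize {cellsize_km}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for r in range(rows):
            fh.write(" ".join(format(v, ".10g") for v in out[r]) + "\n")


def read_ascii_grid(path) -> np.ndarray:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    meta = {}
    data_lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                meta[parts[0].lower()] = float(parts[1])
            else:
                try:
                    data_lines.append([float(p) for p in parts])
                except ValueError as exc:
                    raise GridFormatError(
                        f"{path}: malformed value on line {lineno}"
                    ) from exc
    if "ncols" not in meta or "nrows" not in meta:
        raise GridFormatError(f"{path}: missing ncols/nrows header")
    arr = np.array(data_lines, dtype=float)
    if arr.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise GridFormatError(
            f"{path}: data shape {arr.shape} does not match header "
            f"({int(meta['nrows'])}, {int(meta['ncols'])})"
        )
    nodata = meta.get("nodata_value", NODATA)
    arr[arr == nodata] = np.nan
    return arr


def write_tiff_grid(grid: np.ndarray, path, nodata: float = NODATA) -> None:
    import tifffile

    arr = np.asarray(grid, dtype=np.float32)
    if arr.ndim != 2:
        raise GridFormatError("TIFF grid writer expects a 2-D array")
    out = np.where(np.isnan(arr), np.float32(nodata), arr)
    tifffile.imwrite(path, out)


def read_tiff_grid(path, nodata: float = NODATA) -> np.ndarray:
    import tifffile

    arr = tifffile.imread(path).astype(float)
    if arr.ndim != 2:
        raise GridFormatError(f"{path}: expected a single-band grid")
    arr[arr == nodata] = np.nan
    return arr


def write_grid(grid: np.ndarray, path, cellsize_km: float = 1.0) -> None:
    """Dispatch on extension: .asc -> ASCII grid, .tif/.tiff -> TIFF."""
    suffix = Path(path).suffix.lower()
    if suffix == ".asc":
        write_ascii_grid(grid, path, cellsize_km=cellsize_km)
    elif suffix in (".tif", ".tiff"):
        write_tiff_grid(grid, path)
    else:
        raise GridFormatError(f"unknown grid format {suffix!r}")


def read_grid(path) -> np.ndarray:
    suffix = Path(path).suffix.lower()
    if suffix == ".asc":
        return read_ascii_grid(path)
    if suffix in (".tif", ".tiff"):
        return read_tiff_grid(path)
    raise GridFormatError(f"unknown grid format {suffix!r}")


def read_table(path, required: Optional[Sequence[str]] = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise GridFormatError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
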