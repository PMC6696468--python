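"""Plain-text I/O: ESRI ASCII grids and sample-table CSVs with metadata.

ESRI ASCII is the portable raster interchange format of this workflow:
a six-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by row-major cell values, row 0 at the north edge.
Values are written with 17 significant digits so write -> read -> write
round-trips bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kriging import GridSpec, PredictionGrid

__all__ = [
    "write_esri_ascii",
    "read_esri_ascii",
    "write_prediction_grid",
    "write_samples",
    "read_samples",
]

NODATA = -9999


def write_esri_ascii(path, grid: np.ndarray, spec: GridSpec, nodata: float = NODATA) -> None:
    grid = np.asarray(grid, dtype=float)
    if grid.shape != (spec.n_rows, spec.n_cols):
        raise ValueError("grid shape does not match spec")
    body = np.where(np.isnan(grid), float(nodata), grid)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.x0:.17g}\n")
        fh.write(f"yllcorner {spec.y0:.17g}\n")
        fh.write(f"cellsize {spec.cell_size:.17g}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in body:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_esri_ascii(path) -> tuple[np.ndarray, GridSpec, float]:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    spec = GridSpec(
        header["xllcorner"],
        header["yllcorner"],
        header["cellsize"],
        int(header["nrows"]),
        int(header["ncols"]),
    )
    grid = np.atleast_2d(grid).reshape(spec.n_rows, spec.n_cols)
    nodata = header["nodata_value"]
    grid = np.where(grid == nodata, np.nan, grid)
    return grid, spec, nodata


def write_prediction_grid(outdir, grid: PredictionGrid, stem: str | None = None) -> list[Path]:
    """Write estimate and kriging-variance rasters for one kriged surface."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{grid.variable}_{grid.method.lower()}"
    paths = []
    for suffix, data in (("estimate", grid.estimate), ("variance", grid.kriging_variance)):
        p = outdir / f"{stem}_{suffix}.asc"
        write_esri_ascii(p, data, grid.spec)
        paths.append(p)
    return paths


def write_samples(path, samples: pd.DataFrame, metadata: dict | None = None) -> None:
    """Write a sample table as CSV with '# key: value' metadata header lines."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        samples.to_csv(fh, index=False)


def read_samples(path) -> tuple[pd.DataFrame, dict]:
    """Read a sample CSV, returning the table and any '#' metadata lines."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta
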