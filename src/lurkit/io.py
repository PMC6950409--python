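"""Plain-text raster and vector I/O.

Rasters use the ESRI ASCII grid format (``.asc``): a 6-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
rows of values from the *northern* edge down.  lurkit stores arrays with
row 0 at the southern edge, so rows are flipped on read/write.  Vector
layers round-trip through a CSV with a WKT geometry column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely

from .grid import FeatureRaster, GridSpec

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_vectors_csv",
    "read_vectors_csv",
]

_NODATA = -9999.0


def write_ascii_grid(raster: FeatureRaster, path: str | Path) -> None:
    path = Path(path)
    g = raster.grid
    vals = np.where(np.isfinite(raster.values), raster.values, _NODATA)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_x:.6f}\n"
        f"yllcorner {g.origin_y:.6f}\n"
        f"cellsize {g.cell_size:.6f}\n"
        f"NODATA_value {_NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path, name: str | None = None,
                    units: str = "") -> FeatureRaster:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1].copy()
    nodata = header.get("nodata_value", _NODATA)
    data[data == nodata] = np.nan
    grid = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
    )
    return FeatureRaster(grid=grid, name=name or path.stem,
                         values=data, units=units)


def write_vectors_csv(vectors: Mapping[str, Iterable], path: str | Path) -> None:
    """Vector layers as a CSV with columns ``layer, wkt``."""
    rows = []
    for layer in sorted(vectors):
        for geom in vectors[layer]:
            rows.append({"layer": layer, "wkt": shapely.to_wkt(geom)})
    pd.DataFrame(rows, columns=["layer", "wkt"]).to_csv(path, index=False)


def read_vectors_csv(path: str | Path) -> dict[str, list]:
    df = pd.read_csv(path)
    out: dict[str, list] = {}
    for _, row in df.iterrows():
        out.setdefault(row["layer"], []).append(shapely.from_wkt(row["wkt"]))
    return out
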