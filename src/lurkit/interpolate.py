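"""Inverse-distance-weighted (IDW) interpolation of station meteorology.

Meteorological observations exist only at a handful of stations; the
regression needs them at monitor coordinates and, for mapping, at every
grid cell.  IDW estimates a value as the weighted mean of station values
with weights ``d^-power``, which makes it an exact interpolator at the
stations and keeps every estimate inside the observed value range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import FeatureRaster, GridSpec

__all__ = ["IDWConfig", "idw", "idw_many", "idw_surface"]


@dataclass(frozen=True)
class IDWConfig:
    """IDW parameters.

    power
        Distance-decay exponent; 2 is the conventional default.
    max_neighbors
        Use only the k nearest stations (None = all stations).
    snap_tolerance
        Queries within this distance (m) of a station return that
        station's value exactly, avoiding division by zero.
    """

    power: float = 2.0
    max_neighbors: int | None = None
    snap_tolerance: float = 1.0

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("power must be positive")
        if self.max_neighbors is not None and self.max_neighbors < 1:
            raise ValueError("max_neighbors must be >= 1 when finite")
        if self.snap_tolerance < 0:
            raise ValueError("snap_tolerance must be non-negative")


def _station_array(stations) -> np.ndarray:
    if isinstance(stations, pd.DataFrame):
        arr = stations[["x", "y", "value"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(stations, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("stations must be (n, 3) rows of (x, y, value)")
    arr = arr[np.isfinite(arr[:, 2])]
    if len(arr) == 0:
        raise ValueError("no station has a finite value")
    return arr


def idw_many(stations, queries, cfg: IDWConfig | None = None) -> np.ndarray:
    """IDW estimate at each query point.  ``stations`` is an (n, 3) array
    of (x, y, value) or a DataFrame with those columns."""
    cfg = cfg or IDWConfig()
    st = _station_array(stations)
    q = np.atleast_2d(np.asarray(queries, dtype=float))
    d = np.hypot(q[:, None, 0] - st[None, :, 0], q[:, None, 1] - st[None, :, 1])

    if cfg.max_neighbors is not None and cfg.max_neighbors < len(st):
        k = cfg.max_neighbors
        keep = np.argpartition(d, k - 1, axis=1)[:, :k]
        d = np.take_along_axis(d, keep, axis=1)
        vals = st[:, 2][keep]
    else:
        vals = np.broadcast_to(st[:, 2], d.shape)

    out = np.empty(len(q))
    snapped = d <= cfg.snap_tolerance
    with np.errstate(divide="ignore"):
        w = d ** (-cfg.power)
    for i in range(len(q)):
        if snapped[i].any():
            out[i] = vals[i][np.argmin(d[i])]
        else:
            wi = w[i]
            out[i] = float(np.dot(wi, vals[i]) / wi.sum())
    return out


def idw(stations, query, cfg: IDWConfig | None = None) -> float:
    """IDW estimate at a single (x, y) query point."""
    return float(idw_many(stations, [query], cfg)[0])


def idw_surface(stations, grid: GridSpec, cfg: IDWConfig | None = None,
                name: str = "idw") -> FeatureRaster:
    """IDW evaluated at every cell center; identical to pointwise
    :func:`idw` calls at the same coordinates."""
    X, Y = grid.cell_centers()
    vals = idw_many(stations, np.column_stack([X.ravel(), Y.ravel()]), cfg)
    return FeatureRaster(grid=grid, name=name, values=vals.reshape(grid.shape))
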