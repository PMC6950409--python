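"""Buffer-based geospatial predictors.

A land-use-regression design needs, for every monitoring site, summaries
of the surrounding landscape at a ladder of circular buffer radii:
summed class area (e.g. hectares of residential land within 4250 m),
mean vegetation index within a radius, and Euclidean distance to the
nearest point/line feature (roads, railways, airports).  The same
summaries computed at *every* cell give the predictor rasters needed to
map the fitted model.

The circular buffer is realised as a focal (moving-window) statistic: a
cell belongs to the kernel iff its *center* lies within ``radius`` of
the focal cell's center — the circle semantics of standard GIS focal
statistics.  At the grid edge the statistic uses in-grid kernel cells
only; cells whose whole neighborhood is missing yield NaN.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely import Point
from shapely.strtree import STRtree

from .grid import FeatureRaster, GridSpec

__all__ = [
    "DEFAULT_LADDER",
    "BufferLadder",
    "circular_kernel",
    "focal_stat",
    "focal_at_points",
    "nearest_distance",
    "nearest_distance_raster",
    "extract_at",
    "build_feature_stack",
    "parse_feature_name",
]

#: Default buffer-radius ladder in meters: the 250–5000 m range at the
#: spacings that appear in published LUR variable tables.
DEFAULT_LADDER: tuple[float, ...] = (
    250, 500, 750, 1000, 1250, 1500, 1750, 2000,
    2500, 3000, 4000, 4250, 4750, 5000,
)


@dataclass(frozen=True)
class BufferLadder:
    """Strictly increasing ladder of circular-buffer radii (meters)."""

    radii: tuple[float, ...] = DEFAULT_LADDER

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        if len(radii) == 0:
            raise ValueError("ladder must contain at least one radius")
        if any(r <= 0 for r in radii):
            raise ValueError("all radii must be positive")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("radii must be strictly increasing")
        object.__setattr__(self, "radii", radii)

    def __iter__(self):
        return iter(self.radii)

    def __len__(self) -> int:
        return len(self.radii)


def circular_kernel(radius: float, cell_size: float) -> np.ndarray:
    """Integer cell offsets (di, dj) whose center-to-center distance is
    ``<= radius``, in row-major order.

    The focal cell (0, 0) is always included.  Membership compares
    ``(di^2 + dj^2) * cell_size^2 <= radius^2`` so a cell center exactly
    on the circle is inside.
    """
    if radius <= 0 or cell_size <= 0:
        raise ValueError("radius and cell_size must be positive")
    reach = int(np.floor(radius / cell_size))
    di, dj = np.meshgrid(
        np.arange(-reach, reach + 1), np.arange(-reach, reach + 1), indexing="ij"
    )
    inside = (di * di + dj * dj) * (cell_size * cell_size) <= radius * radius
    return np.column_stack([di[inside], dj[inside]])


def _kernel_mask(radius: float, cell_size: float) -> tuple[int, np.ndarray]:
    """(reach, boolean mask of shape (2*reach+1, 2*reach+1)) for the kernel."""
    offsets = circular_kernel(radius, cell_size)
    reach = int(np.floor(radius / cell_size))
    mask = np.zeros((2 * reach + 1, 2 * reach + 1), dtype=bool)
    mask[offsets[:, 0] + reach, offsets[:, 1] + reach] = True
    return reach, mask


def focal_stat(raster: FeatureRaster, radius: float, stat: str = "mean") -> FeatureRaster:
    """Circular focal statistic of a raster.

    ``stat`` is ``"sum"`` or ``"mean"``, taken over the in-grid, finite
    cells of the circular kernel centered at each cell.  NaN cells are
    treated as missing; a cell whose entire kernel is missing is NaN in
    the output.
    """
    if stat not in ("sum", "mean"):
        raise ValueError(f"unsupported stat {stat!r}; use 'sum' or 'mean'")
    sums, counts = _focal_sum_count(raster.values, radius, raster.grid.cell_size)
    with np.errstate(invalid="ignore", divide="ignore"):
        if stat == "sum":
            out = np.where(counts > 0, sums, np.nan)
        else:
            out = np.where(counts > 0, sums / counts, np.nan)
    name = f"{raster.name}_{_fmt_radius(radius)}"
    return FeatureRaster(grid=raster.grid, name=name, values=out, units=raster.units)


def _focal_sum_count(values: np.ndarray, radius: float, cell_size: float):
    """Kernel sums and finite-cell counts, accumulated offset-by-offset in
    row-major kernel order (the same order a per-cell loop would use)."""
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    valid = np.isfinite(values)
    v0 = np.where(valid, values, 0.0)
    sums = np.zeros_like(v0)
    counts = np.zeros(values.shape, dtype=np.int64)
    for di, dj in circular_kernel(radius, cell_size):
        src_r = slice(max(di, 0), min(n_rows + di, n_rows))
        dst_r = slice(max(-di, 0), min(n_rows - di, n_rows))
        src_c = slice(max(dj, 0), min(n_cols + dj, n_cols))
        dst_c = slice(max(-dj, 0), min(n_cols - dj, n_cols))
        if src_r.start >= src_r.stop or src_c.start >= src_c.stop:
            continue
        sums[dst_r, dst_c] += v0[src_r, src_c]
        counts[dst_r, dst_c] += valid[src_r, src_c]
    return sums, counts


def focal_at_points(
    values: np.ndarray,
    grid: GridSpec,
    radius: float,
    coords: Sequence[tuple[float, float]],
    stat: str = "mean",
) -> np.ndarray:
    """Circular focal statistic evaluated only at the cells containing
    ``coords``.

    ``values`` may be 2-D ``(rows, cols)`` or 3-D ``(time, rows, cols)``;
    the result has shape ``(n_points,)`` or ``(time, n_points)``.  Much
    cheaper than :func:`focal_stat` when only monitor locations matter.
    """
    if stat not in ("sum", "mean"):
        raise ValueError(f"unsupported stat {stat!r}; use 'sum' or 'mean'")
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 2
    if squeeze:
        values = values[None, :, :]
    _, n_rows, n_cols = values.shape
    if (n_rows, n_cols) != grid.shape:
        raise ValueError("values shape does not match grid")
    reach, mask = _kernel_mask(radius, grid.cell_size)

    coords = np.asarray(coords, dtype=float)
    rows, cols = grid.index_of(coords[:, 0], coords[:, 1])
    out = np.full((values.shape[0], len(coords)), np.nan)
    for k, (r, c) in enumerate(zip(np.atleast_1d(rows), np.atleast_1d(cols))):
        r0, r1 = max(r - reach, 0), min(r + reach + 1, n_rows)
        c0, c1 = max(c - reach, 0), min(c + reach + 1, n_cols)
        m = mask[r0 - (r - reach): r1 - (r - reach), c0 - (c - reach): c1 - (c - reach)]
        window = values[:, r0:r1, c0:c1]
        sel = np.where(m[None, :, :], window, np.nan)
        with np.errstate(invalid="ignore"):
            if stat == "sum":
                got = np.nansum(sel, axis=(1, 2))
                got[~np.isfinite(sel).any(axis=(1, 2))] = np.nan
            else:
                got = np.nanmean(sel, axis=(1, 2))
        out[:, k] = got
    return out[0] if squeeze else out


def _as_geometries(features: Iterable) -> list:
    geoms = []
    for f in features:
        if isinstance(f, shapely.Geometry):
            geoms.append(f)
        else:
            x, y = f
            geoms.append(Point(float(x), float(y)))
    return geoms


def nearest_distance(features: Iterable, query: tuple[float, float]) -> float:
    """Euclidean distance from ``query`` to the nearest feature
    (point-to-point, or point-to-segment for line features)."""
    geoms = _as_geometries(features)
    if not geoms:
        raise ValueError("feature set is empty")
    p = Point(float(query[0]), float(query[1]))
    return float(min(p.distance(g) for g in geoms))


def _nearest_distance_many(features: Iterable, points: np.ndarray) -> np.ndarray:
    geoms = _as_geometries(features)
    if not geoms:
        raise ValueError("feature set is empty")
    pts = shapely.points(points[:, 0], points[:, 1])
    tree = STRtree(geoms)
    idx = tree.nearest(pts)
    geom_arr = np.asarray(geoms, dtype=object)
    return shapely.distance(pts, geom_arr[idx])


def nearest_distance_raster(features: Iterable, grid: GridSpec, name: str) -> FeatureRaster:
    """Raster of nearest-feature distance at every cell center (meters)."""
    X, Y = grid.cell_centers()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    d = _nearest_distance_many(features, pts).reshape(grid.shape)
    return FeatureRaster(grid=grid, name=f"{name}_nearest", values=d, units="m")


def extract_at(raster: FeatureRaster, coords: Sequence[tuple[float, float]],
               labels: Sequence[str] | None = None) -> np.ndarray:
    """Raster value of the cell containing each coordinate (no interpolation).

    Out-of-bounds coordinates raise ``ValueError`` naming the offending
    station label when ``labels`` is given.
    """
    coords = np.asarray(coords, dtype=float)
    inside = np.atleast_1d(raster.grid.contains(coords[:, 0], coords[:, 1]))
    if not inside.all():
        bad = int(np.argwhere(~inside).ravel()[0])
        who = labels[bad] if labels is not None else f"#{bad}"
        raise ValueError(
            f"station {who!r} at ({coords[bad, 0]:g}, {coords[bad, 1]:g}) "
            f"lies outside the grid"
        )
    rows, cols = raster.grid.index_of(coords[:, 0], coords[:, 1])
    return raster.values[rows, cols]


def build_feature_stack(
    landuse: FeatureRaster | None = None,
    class_map: Mapping[int, str] | None = None,
    ndvi: FeatureRaster | None = None,
    vectors: Mapping[str, Iterable] | None = None,
    ladder: BufferLadder | Sequence[float] = DEFAULT_LADDER,
    landuse_unit: str = "hectares",
) -> dict[str, FeatureRaster]:
    """Full predictor-raster collection for a scene.

    Produces one raster per (land-use class x radius) with summed class
    area, one per (NDVI x radius) with the buffer-mean index, and one
    nearest-distance raster per vector layer.  Names follow the
    machine-parseable ``<Layer>_<radius>m`` / ``<Layer>_nearest``
    convention (see :func:`parse_feature_name`).

    ``landuse_unit`` is ``"hectares"`` (default), ``"m2"`` or
    ``"fraction"`` (share of the in-grid buffer area).
    """
    ladder = ladder if isinstance(ladder, BufferLadder) else BufferLadder(tuple(ladder))
    stack: dict[str, FeatureRaster] = {}
    grids = [r.grid for r in (landuse, ndvi) if r is not None]
    if len({g for g in grids}) > 1:
        raise ValueError("landuse and ndvi rasters must share a grid")

    if landuse is not None:
        if class_map is None:
            raise ValueError("class_map is required with a land-use raster")
        cell_area = landuse.grid.cell_area
        for code, cls in sorted(class_map.items()):
            mask = landuse.with_values(
                (landuse.values == code).astype(float), name=cls)
            for r in ladder:
                sums, counts = _focal_sum_count(
                    mask.values, r, landuse.grid.cell_size)
                if landuse_unit == "hectares":
                    vals, units = sums * cell_area / 1e4, "ha"
                elif landuse_unit == "m2":
                    vals, units = sums * cell_area, "m2"
                elif landuse_unit == "fraction":
                    with np.errstate(invalid="ignore", divide="ignore"):
                        vals = np.where(counts > 0, sums / counts, np.nan)
                    units = "fraction"
                else:
                    raise ValueError(f"unknown landuse_unit {landuse_unit!r}")
                name = f"{cls}_{_fmt_radius(r)}"
                stack[name] = FeatureRaster(
                    grid=landuse.grid, name=name, values=vals, units=units)

    if ndvi is not None:
        for r in ladder:
            out = focal_stat(ndvi.with_values(ndvi.values, name="NDVI"), r, "mean")
            out.units = "index"
            stack[out.name] = out

    if vectors:
        grid = grids[0] if grids else None
        if grid is None:
            raise ValueError("vector-only stacks need a raster to define the grid")
        for layer in sorted(vectors):
            out = nearest_distance_raster(vectors[layer], grid, layer)
            stack[out.name] = out
    return stack


_NAME_RE = re.compile(r"^(?P<layer>.+)_(?P<radius>\d+(?:\.\d+)?)m$")


def parse_feature_name(name: str) -> dict:
    """Decompose a feature name into layer / kind / radius.

    ``Residential_4250m`` -> buffered layer with radius 4250;
    ``Airport_nearest`` -> distance layer; anything else is a plain
    (meteorology, co-pollutant, season) column.
    """
    if name.endswith("_nearest"):
        return {"layer": name[: -len("_nearest")], "kind": "distance", "radius": None}
    m = _NAME_RE.match(name)
    if m:
        return {
            "layer": m.group("layer"),
            "kind": "buffered",
            "radius": float(m.group("radius")),
        }
    return {"layer": name, "kind": "plain", "radius": None}


def _fmt_radius(radius: float) -> str:
    r = float(radius)
    return f"{int(r)}m" if r.is_integer() else f"{r:g}m"
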