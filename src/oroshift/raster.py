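"""Minimal raster plumbing: grids, boundaries, clipping, and bilinear alignment.

Every downstream statistic in this package operates on plain collections of
cell values; this module is the only place that knows about raster geometry.
Grids are single-band, north-up, square-celled rasters: ``origin`` is the
(x, y) of the upper-left *corner*, row indices increase southward, and the
center of cell (row, col) sits at ``(origin_x + (col + 0.5) * cell_size,
origin_y - (row + 0.5) * cell_size)``.

GeoTIFF I/O is deliberately small: a single band plus the ModelPixelScale,
ModelTiepoint and GDAL nodata tags, which is all the synthetic fixtures and
pre-co-registered analysis rasters require.  Boundaries are GeoJSON
(Polygon/MultiPolygon geometries, bare or wrapped in a Feature).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import DisjointGridsError, EmptyClipError

__all__ = [
    "Grid",
    "RangeBoundary",
    "read_geotiff",
    "write_geotiff",
    "read_boundary",
    "write_boundary",
    "clip_values",
    "align_bilinear",
    "values_to_csv",
]

# private GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113


@dataclass
class Grid:
    """A 2-D raster with a nodata mask and square-cell geometry."""

    values: np.ndarray
    nodata_mask: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = "synthetic-local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.values.shape != self.nodata_mask.shape:
            raise ValueError("values and nodata_mask must have identical shape")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("every unmasked value must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of all cell centers, each of grid shape."""
        rows, cols = self.shape
        x = self.origin[0] + (np.arange(cols) + 0.5) * self.cell_size
        y = self.origin[1] - (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        rows, cols = self.shape
        return (
            self.origin[0],
            self.origin[1] - rows * self.cell_size,
            self.origin[0] + cols * self.cell_size,
            self.origin[1],
        )

    def unmasked_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]


@dataclass
class RangeBoundary:
    """A mountain-range outline: polygon plus identifying metadata."""

    polygon: BaseGeometry
    name: str = ""
    id: str = ""
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.polygon.is_valid:
            raise ValueError(f"boundary polygon for {self.id!r} is not valid")
        if not self.polygon.area > 0:
            raise ValueError(f"boundary polygon for {self.id!r} has zero area")


def write_geotiff(grid: Grid, path: str | Path, nodata: float = -9999.0) -> Path:
    """Write a single-band GeoTIFF carrying the grid's geometry tags."""
    path = Path(path)
    data = grid.values.astype(np.float64).copy()
    data[grid.nodata_mask] = nodata
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (
            _MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0),
        ),
        (_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(
        path,
        data,
        description=json.dumps({"crs_tag": grid.crs_tag}),
        extratags=extratags,
    )
    return path


def read_geotiff(path: str | Path) -> Grid:
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or any
    GeoTIFF exposing pixel-scale/tiepoint tags), honoring the nodata tag."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        if values.ndim != 2:
            raise ValueError(f"{path}: expected a single-band raster")
        tags = page.tags
        scale = tags[_MODEL_PIXEL_SCALE].value if _MODEL_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
        tie = (
            tags[_MODEL_TIEPOINT].value
            if _MODEL_TIEPOINT in tags
            else (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        )
        nodata = float(tags[_GDAL_NODATA].value) if _GDAL_NODATA in tags else np.nan
        crs_tag = "unknown"
        desc = page.description or ""
        if desc:
            try:
                crs_tag = json.loads(desc).get("crs_tag", "unknown")
            except (json.JSONDecodeError, AttributeError):
                crs_tag = desc
    mask = ~np.isfinite(values)
    if np.isfinite(nodata):
        mask |= values == nodata
    values = np.where(mask, 0.0, values)
    return Grid(
        values=values,
        nodata_mask=mask,
        cell_size=float(scale[0]),
        origin=(float(tie[3]), float(tie[4])),
        crs_tag=crs_tag,
    )


def read_boundary(path: str | Path) -> RangeBoundary:
    """Read a range boundary from a GeoJSON file.

    Accepts a bare geometry, a Feature, or a FeatureCollection (first feature).
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        doc = doc["features"][0]
    if doc.get("type") == "Feature":
        props = doc.get("properties") or {}
        geom = shape(doc["geometry"])
    else:
        props = {}
        geom = shape(doc)
    return RangeBoundary(
        polygon=geom,
        name=str(props.get("name", "")),
        id=str(props.get("id", Path(path).stem)),
        properties=props,
    )


def write_boundary(boundary: RangeBoundary, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "type": "Feature",
        "properties": {"name": boundary.name, "id": boundary.id, **boundary.properties},
        "geometry": mapping(boundary.polygon),
    }
    path.write_text(json.dumps(doc))
    return path


def clip_values(grid: Grid, boundary: RangeBoundary) -> np.ndarray:
    """Unmasked cell values whose cell centers fall inside the boundary.

    The center rule — a cell belongs to the range iff its center is inside
    the polygon — is the conventional raster-clip behavior and is applied
    deterministically in row-major order.

    Raises
    ------
    EmptyClipError
        If no cell center falls inside the polygon.
    """
    cx, cy = grid.cell_centers()
    inside = shapely.contains_xy(boundary.polygon, cx.ravel(), cy.ravel())
    if not inside.any():
        raise EmptyClipError(
            f"boundary {boundary.id!r} contains no cell centers of the grid (empty clip)"
        )
    keep = inside & ~grid.nodata_mask.ravel()
    return grid.values.ravel()[keep]


def align_bilinear(src: Grid, template: Grid) -> Grid:
    """Resample ``src`` onto ``template``'s geometry by bilinear interpolation.

    Each output value interpolates the four surrounding ``src`` cell centers;
    output cells outside src coverage, or touching a masked src cell, are
    masked.  Raises :class:`DisjointGridsError` when nothing overlaps.
    """
    tx, ty = template.cell_centers()
    # fractional src cell-center indices of template centers
    fx = (tx - src.origin[0]) / src.cell_size - 0.5
    fy = (src.origin[1] - ty) / src.cell_size - 0.5
    rows, cols = src.shape
    in_cov = (fx >= 0) & (fx <= cols - 1) & (fy >= 0) & (fy <= rows - 1)
    if not in_cov.any():
        raise DisjointGridsError("source grid does not overlap the template grid")
    x0 = np.clip(np.floor(fx).astype(int), 0, max(cols - 2, 0))
    y0 = np.clip(np.floor(fy).astype(int), 0, max(rows - 2, 0))
    x1 = np.minimum(x0 + 1, cols - 1)
    y1 = np.minimum(y0 + 1, rows - 1)
    wx = np.clip(fx - x0, 0.0, 1.0)
    wy = np.clip(fy - y0, 0.0, 1.0)

    v = src.values
    out = (
        v[y0, x0] * (1 - wy) * (1 - wx)
        + v[y0, x1] * (1 - wy) * wx
        + v[y1, x0] * wy * (1 - wx)
        + v[y1, x1] * wy * wx
    )
    m = src.nodata_mask
    touched_nodata = m[y0, x0] | m[y0, x1] | m[y1, x0] | m[y1, x1]
    mask = ~in_cov | touched_nodata
    out = np.where(mask, 0.0, out)
    return Grid(
        values=out,
        nodata_mask=mask,
        cell_size=template.cell_size,
        origin=template.origin,
        crs_tag=template.crs_tag,
    )


def values_to_csv(range_id: str, values: np.ndarray, path: str | Path) -> Path:
    """Export a clipped value collection as a two-column CSV."""
    path = Path(path)
    pd.DataFrame({"range_id": range_id, "value": np.asarray(values)}).to_csv(
        path, index=False, float_format="%.10g"
    )
    return path
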