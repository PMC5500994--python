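"""Data model and I/O for DSM/orthomosaic rasters and tabular/vector tree outputs.

A digital surface model (DSM) is a single-band raster of elevations in meters
above a datum; trees appear as local elevation highs.  The model here is
deliberately minimal: a north-up, axis-aligned affine transform (no rotation or
shear), square pixels, and an explicit nodata mask.  GeoTIFF round-tripping is
implemented with :mod:`tifffile` using the standard GeoTIFF tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus GDAL's nodata tag.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GridTransform",
    "DsmGrid",
    "MultiLayerScene",
    "OrchardConfig",
    "CoRegistrationError",
    "read_dsm",
    "write_dsm",
    "write_rgb",
    "read_scene",
    "write_tree_outputs",
    "read_tree_table",
    "NODATA_DEFAULT",
]

NODATA_DEFAULT = -9999.0

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113


class CoRegistrationError(ValueError):
    """Raised when two rasters that must share a grid do not."""


@dataclass(frozen=True)
class GridTransform:
    """Axis-aligned, north-up mapping between pixel indices and map coordinates.

    ``x_min``/``y_max`` are the outer edges of the top-left pixel; pixel
    *centers* carry the coordinates used throughout the package, i.e. pixel
    (row, col) sits at ``(x_min + (col + 0.5) * pixel_size,
    y_max - (row + 0.5) * pixel_size)``.
    """

    x_min: float
    y_max: float
    pixel_size: float

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    def xy(self, row, col):
        """Map coordinates of pixel centers (vectorized)."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.x_min + (col + 0.5) * self.pixel_size
        y = self.y_max - (row + 0.5) * self.pixel_size
        return x, y

    def rowcol(self, x, y):
        """Pixel indices containing map coordinates (floor convention)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_min) / self.pixel_size).astype(int)
        row = np.floor((self.y_max - y) / self.pixel_size).astype(int)
        return row, col

    def isclose(self, other: "GridTransform", tol: float = 1e-9) -> bool:
        return (
            abs(self.x_min - other.x_min) <= tol
            and abs(self.y_max - other.y_max) <= tol
            and abs(self.pixel_size - other.pixel_size) <= tol
        )


@dataclass
class DsmGrid:
    """Geo-referenced elevation raster with a nodata mask.

    Parameters
    ----------
    elevations
        2-D float array, meters above datum.  Values under ``nodata_mask`` are
        ignored everywhere in the package.
    transform
        Pixel-to-map transform (axis aligned, north up).
    nodata_mask
        Boolean array, ``True`` where the raster carries no data.
    crs_label
        Free-text CRS identifier, e.g. ``"EPSG:32630"`` (UTM zone 30N, WGS84).
        Empty string means "pixel units" (not geo-referenced).
    """

    elevations: np.ndarray
    transform: GridTransform
    nodata_mask: np.ndarray | None = None
    crs_label: str = ""

    def __post_init__(self) -> None:
        self.elevations = np.asarray(self.elevations, dtype=np.float64)
        if self.elevations.ndim != 2:
            raise ValueError("elevations must be a 2-D array")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.elevations)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.elevations.shape:
                raise ValueError("nodata_mask shape must match elevations")
            self.nodata_mask = self.nodata_mask | ~np.isfinite(self.elevations)
        if not np.all(np.isfinite(self.elevations[~self.nodata_mask])):
            raise ValueError("elevations must be finite where nodata_mask is False")

    @property
    def pixel_size(self) -> float:
        return self.transform.pixel_size

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevations.shape

    @property
    def pixel_area(self) -> float:
        return self.transform.pixel_size ** 2

    def valid(self) -> np.ndarray:
        """Elevations with nodata replaced by NaN."""
        out = self.elevations.copy()
        out[self.nodata_mask] = np.nan
        return out


@dataclass
class MultiLayerScene:
    """A DSM plus an optional co-registered RGB orthomosaic for one date.

    Mirrors a 4-band multi-layer stack (Red, Green, Blue and DSM) produced by
    UAV photogrammetry; the RGB bands are carried only for visual QC, all
    analysis is height-driven.
    """

    dsm: DsmGrid
    rgb: np.ndarray | None = None
    date_label: str = ""

    def __post_init__(self) -> None:
        if self.rgb is not None:
            self.rgb = np.asarray(self.rgb)
            if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
                raise CoRegistrationError("rgb must be a (rows, cols, 3) array")
            if self.rgb.shape[:2] != self.dsm.shape:
                raise CoRegistrationError(
                    f"rgb shape {self.rgb.shape[:2]} does not match "
                    f"dsm shape {self.dsm.shape}"
                )


@dataclass
class OrchardConfig:
    """Plantation layout: a regular grid of trees in rows.

    The within-row axis points along ``row_azimuth_deg`` (degrees
    counter-clockwise from map east); successive trees in a row are
    ``tree_spacing_m`` apart and successive rows ``row_spacing_m`` apart.
    Grid node (row 1, col 1) sits at ``origin_xy``.  ``treatment_blocks``
    assigns contiguous 1-based row ranges to named pruning treatments and must
    partition rows 1..n_rows.
    """

    origin_xy: tuple[float, float] = (485740.0, 4217700.0)
    row_azimuth_deg: float = 0.0
    row_spacing_m: float = 8.0
    tree_spacing_m: float = 4.0
    n_rows: int = 27
    n_cols: int = 24
    treatment_blocks: list[tuple[int, int, str]] = field(
        default_factory=lambda: [
            (1, 9, "traditional"),
            (10, 18, "adapted"),
            (19, 27, "mechanical"),
        ]
    )

    def __post_init__(self) -> None:
        if self.row_spacing_m <= 0 or self.tree_spacing_m <= 0:
            raise ValueError("spacings must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        covered: list[int] = []
        for lo, hi, _name in self.treatment_blocks:
            if lo > hi:
                raise ValueError(f"empty treatment block ({lo}, {hi})")
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(1, self.n_rows + 1)):
            raise ValueError(
                "treatment_blocks must partition rows 1..n_rows without overlap"
            )

    @property
    def n_trees(self) -> int:
        return self.n_rows * self.n_cols

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit vectors of the within-row axis and the across-row axis."""
        a = math.radians(self.row_azimuth_deg)
        u = np.array([math.cos(a), math.sin(a)])  # along a row
        v = np.array([-math.sin(a), math.cos(a)])  # row-to-row
        return u, v

    def node_xy(self, row, col):
        """Map coordinates of grid node(s); row/col are 1-based."""
        u, v = self.axes()
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.origin_xy[0] + (col - 1) * self.tree_spacing_m * u[0] + (row - 1) * self.row_spacing_m * v[0]
        y = self.origin_xy[1] + (col - 1) * self.tree_spacing_m * u[1] + (row - 1) * self.row_spacing_m * v[1]
        return x, y

    def grid_coords(self, x, y):
        """Inverse of :meth:`node_xy`: fractional (row, col), 1-based."""
        u, v = self.axes()
        dx = np.asarray(x, dtype=float) - self.origin_xy[0]
        dy = np.asarray(y, dtype=float) - self.origin_xy[1]
        along = dx * u[0] + dy * u[1]
        across = dx * v[0] + dy * v[1]
        return 1.0 + across / self.row_spacing_m, 1.0 + along / self.tree_spacing_m

    def treatment_for_row(self, row: int) -> str:
        for lo, hi, name in self.treatment_blocks:
            if lo <= row <= hi:
                return name
        raise KeyError(f"row {row} not covered by treatment_blocks")


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def _epsg_from_label(crs_label: str) -> int | None:
    label = crs_label.strip().upper()
    if label.startswith("EPSG:"):
        try:
            return int(label.split(":", 1)[1])
        except ValueError:
            return None
    return None


def _geotiff_extratags(transform: GridTransform, crs_label: str,
                       nodata: float | None) -> list:
    px = float(transform.pixel_size)
    tags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (px, px, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(transform.x_min), float(transform.y_max), 0.0)),
    ]
    epsg = _epsg_from_label(crs_label)
    keys = [(1024, 0, 1, 1), (1025, 0, 1, 1)]  # ModelTypeProjected, RasterPixelIsArea
    if epsg is not None:
        keys.append((3072, 0, 1, epsg))  # ProjectedCSTypeGeoKey
    directory = [1, 1, 0, len(keys)]
    for entry in keys:
        directory.extend(entry)
    tags.append((_TAG_GEO_KEY_DIRECTORY, "H", len(directory), tuple(directory)))
    if nodata is not None:
        text = f"{nodata:g}"
        tags.append((_TAG_GDAL_NODATA, "s", len(text) + 1, text))
    return tags


def write_dsm(grid: DsmGrid, path: str | Path, nodata: float = NODATA_DEFAULT) -> None:
    """Write a single-band float32 GeoTIFF; nodata pixels get ``nodata``."""
    data = grid.elevations.astype(np.float32)
    data = np.where(grid.nodata_mask, np.float32(nodata), data)
    tifffile.imwrite(
        Path(path), data,
        extratags=_geotiff_extratags(grid.transform, grid.crs_label, nodata),
    )


def write_rgb(rgb: np.ndarray, transform: GridTransform, path: str | Path,
              crs_label: str = "") -> None:
    """Write a 3-band 8-bit GeoTIFF co-registered with a DSM."""
    rgb = np.asarray(rgb, dtype=np.uint8)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("rgb must be (rows, cols, 3)")
    tifffile.imwrite(
        Path(path), rgb, photometric="rgb",
        extratags=_geotiff_extratags(transform, crs_label, None),
    )


def _read_geotiff(path: str | Path):
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags

        def tag_value(code):
            tag = tags.get(code)
            return None if tag is None else tag.value

        scale = tag_value(_TAG_MODEL_PIXEL_SCALE)
        tiepoint = tag_value(_TAG_MODEL_TIEPOINT)
        nodata_tag = tag_value(_TAG_GDAL_NODATA)
        geokeys = tag_value(_TAG_GEO_KEY_DIRECTORY)
    crs_label = ""
    if geokeys is not None:
        vals = list(geokeys)
        nkeys = vals[3]
        for i in range(nkeys):
            key_id, loc, count, value = vals[4 + 4 * i: 8 + 4 * i]
            if key_id == 3072 and loc == 0:
                crs_label = f"EPSG:{value}"
    if scale is not None and tiepoint is not None:
        sx, sy = float(scale[0]), float(scale[1])
        if not math.isclose(sx, sy, rel_tol=1e-6):
            raise ValueError(f"non-square pixels ({sx} x {sy}) are not supported")
        tp = tiepoint
        # tiepoint maps raster (col tp[0], row tp[1]) to map (tp[3], tp[4])
        x_min = float(tp[3]) - float(tp[0]) * sx
        y_max = float(tp[4]) + float(tp[1]) * sy
        transform = GridTransform(x_min=x_min, y_max=y_max, pixel_size=sx)
    else:
        warnings.warn(
            f"{path}: no GeoTIFF georeferencing tags; proceeding in pixel units",
            stacklevel=3,
        )
        transform = GridTransform(x_min=0.0, y_max=float(data.shape[0]), pixel_size=1.0)
        crs_label = ""
    nodata = None
    if nodata_tag is not None:
        try:
            nodata = float(str(nodata_tag).strip("\x00 "))
        except ValueError:
            nodata = None
    return data, transform, crs_label, nodata


def read_dsm(path: str | Path) -> DsmGrid:
    """Read a single-band GeoTIFF DSM, propagating nodata into the mask."""
    data, transform, crs_label, nodata = _read_geotiff(path)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {data.shape}")
    data = data.astype(np.float64)
    mask = ~np.isfinite(data)
    if nodata is not None:
        mask |= data == nodata
    if not crs_label:
        warnings.warn(f"{path}: raster has no CRS; coordinates are unit-less",
                      stacklevel=2)
    return DsmGrid(elevations=data, transform=transform, nodata_mask=mask,
                   crs_label=crs_label)


def read_scene(dsm_path: str | Path, rgb_path: str | Path | None = None,
               date_label: str = "") -> MultiLayerScene:
    """Read a DSM plus optional co-registered RGB orthomosaic as one scene.

    Raises
    ------
    CoRegistrationError
        If the RGB raster's shape or transform differs from the DSM's.
    """
    dsm = read_dsm(dsm_path)
    rgb = None
    if rgb_path is not None:
        data, transform, _crs, _nd = _read_geotiff(rgb_path)
        if data.ndim != 3 or data.shape[2] != 3:
            raise CoRegistrationError(
                f"{rgb_path}: expected a 3-band raster, got shape {data.shape}")
        if data.shape[:2] != dsm.shape:
            raise CoRegistrationError(
                f"RGB shape {data.shape[:2]} does not match DSM shape {dsm.shape}")
        if not transform.isclose(dsm.transform, tol=1e-6):
            raise CoRegistrationError("RGB transform does not match DSM transform")
        rgb = data
    return MultiLayerScene(dsm=dsm, rgb=rgb, date_label=date_label)


# ---------------------------------------------------------------------------
# Tree-record outputs (vector + table)
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "tree_id", "row", "column", "x", "y", "treatment", "date",
    "area_m2", "height_m", "volume_m3", "reliable",
]


def _record_properties(rec) -> dict:
    return {
        "tree_id": int(rec.tree_id),
        "row": int(rec.row),
        "column": int(rec.column),
        "x": float(rec.x),
        "y": float(rec.y),
        "treatment": getattr(rec, "treatment", "") or "",
        "date": getattr(rec, "date_label", "") or "",
        "area_m2": round(float(rec.area_m2), 2),
        "height_m": round(float(rec.height_m), 2),
        "volume_m3": round(float(rec.volume_m3), 2),
        "reliable": bool(getattr(rec, "reliable", True)),
    }


def _record_geometry(rec):
    from shapely.geometry import mapping, Point

    geom = getattr(rec, "geometry", None)
    if geom is None:
        # fall back to a circle with the recorded projected area
        radius = math.sqrt(max(float(rec.area_m2), 1e-6) / math.pi)
        geom = Point(float(rec.x), float(rec.y)).buffer(radius, quad_segs=16)
    return mapping(geom)


def write_tree_outputs(records: Sequence, vector_path: str | Path,
                       table_path: str | Path) -> None:
    """Export per-tree identification, location and geometric features.

    Writes a GeoJSON FeatureCollection (one crown polygon per tree with the
    feature attributes) and a CSV table with one row per tree per date.
    Feature values are formatted to 2 decimals, coordinates at full precision.
    """
    records = list(records)
    if not records:
        raise ValueError("no tree records to write")
    features = [
        {"type": "Feature",
         "geometry": _record_geometry(rec),
         "properties": _record_properties(rec)}
        for rec in records
    ]
    collection = {"type": "FeatureCollection", "features": features}
    crs = next((getattr(r, "crs_label", "") for r in records
                if getattr(r, "crs_label", "")), "")
    if crs:
        collection["crs_label"] = crs
    Path(vector_path).write_text(json.dumps(collection, indent=1))

    rows = []
    for rec in records:
        p = _record_properties(rec)
        p["area_m2"] = f"{float(rec.area_m2):.2f}"
        p["height_m"] = f"{float(rec.height_m):.2f}"
        p["volume_m3"] = f"{float(rec.volume_m3):.2f}"
        p["x"] = repr(float(rec.x))
        p["y"] = repr(float(rec.y))
        rows.append(p)
    frame = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    frame.to_csv(Path(table_path), index=False)


def read_tree_table(path: str | Path) -> list:
    """Read a CSV written by :func:`write_tree_outputs` back into TreeRecords."""
    from .tree_metrics import TreeRecord  # local import avoids a module cycle

    frame = pd.read_csv(Path(path))
    records = []
    for _, row in frame.iterrows():
        records.append(TreeRecord(
            tree_id=int(row["tree_id"]), row=int(row["row"]),
            column=int(row["column"]), x=float(row["x"]), y=float(row["y"]),
            treatment=str(row["treatment"]) if pd.notna(row["treatment"]) else "",
            date_label=str(row["date"]) if pd.notna(row["date"]) else "",
            area_m2=float(row["area_m2"]), height_m=float(row["height_m"]),
            volume_m3=float(row["volume_m3"]), reliable=bool(row["reliable"]),
        ))
    return records
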