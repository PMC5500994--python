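"""Object-based delineation of individual tree crowns from a DSM.

The procedure is height-driven and fully automatic, in three phases:

1. *Chessboard segmentation* — the raster is partitioned into square tiles of
   fixed ground size (default 1 m^2), anchored at the raster origin; edge
   tiles may be smaller.
2. *Coarse classification* — a tile whose DSM standard deviation exceeds a
   threshold (default 0.10 m, strict inequality) is a tree tile: canopy
   surfaces are rough/steep at the meter scale while bare soil is flat.  The
   SD is the population (divide-by-N) statistic over valid pixels.
3. *Border refinement* — tiles on the tree/soil interface are re-examined at
   the pixel level.  The border zone comprises tree tiles edge-adjacent to
   soil tiles and vice versa (both sides of the interface, so that spurious
   interior "soil" tiles on smooth crown tops are also re-examined).  Each
   border pixel is assigned by comparing its DSM value to the surrounding
   soil and tree values within a circular window:

   * ``"height-above-soil"`` (default): tree iff the pixel exceeds the local
     bare-soil mean by more than ``soil_margin_m``.  Robust on smooth crowns,
     where the alternative rule misplaces the low canopy skirt.
   * ``"nearest-mean"``: tree iff the pixel is strictly closer to the local
     tree mean than to the local soil mean (ties go to soil).

   The refined tree pixels are labeled into 8-connected components; components
   below a minimum area are discarded as noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .raster_model import DsmGrid, GridTransform, MultiLayerScene, OrchardConfig

__all__ = [
    "Tile",
    "TreeMask",
    "DelineationParams",
    "chessboard_segment",
    "coarse_classify",
    "refine_borders",
    "delineate",
    "nearest_mean_is_tree",
]


@dataclass
class Tile:
    """One chessboard tile: a pixel window plus its classification."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    tile_row: int
    tile_col: int
    sd_dsm: float | None = None
    label: str = "unassigned"  # tree | bare_soil | border | unassigned

    @property
    def window(self) -> tuple[slice, slice]:
        return slice(self.row_start, self.row_stop), slice(self.col_start, self.col_stop)

    @property
    def n_pixels(self) -> int:
        return (self.row_stop - self.row_start) * (self.col_stop - self.col_start)


@dataclass
class TreeMask:
    """Labeled crown raster: 0 = bare soil, k > 0 = tree k (contiguous)."""

    labels: np.ndarray
    n_trees: int
    transform: GridTransform
    crs_label: str = ""

    @property
    def pixel_size(self) -> float:
        return self.transform.pixel_size


@dataclass
class DelineationParams:
    """Thresholds of the delineation; defaults mirror the field protocol."""

    tile_size_m: float = 1.0
    sd_threshold_m: float = 0.10
    window_radius_m: float = 1.5
    rule: str = "height-above-soil"
    soil_margin_m: float = 0.10
    min_tree_area_m2: float = 0.5
    include_soil_side: bool = True
    split_merged: bool = False  # optional grid-seeded watershed split


def _tile_edges(n_pixels: int, tile_px: float) -> list[int]:
    edges = [0]
    i = 1
    while True:
        e = min(n_pixels, int(math.floor(i * tile_px + 1e-9)))
        if e <= edges[-1]:
            e = edges[-1] + 1
        edges.append(min(e, n_pixels))
        if edges[-1] >= n_pixels:
            break
        i += 1
    return edges


def chessboard_segment(dsm: DsmGrid, tile_size_m: float = 1.0) -> list[Tile]:
    """Partition the raster into square tiles of ``tile_size_m`` ground size.

    Tiles are anchored at the raster origin (top-left); right/bottom edge
    tiles are truncated.  Only the DSM band drives later steps.
    """
    px = dsm.pixel_size
    if tile_size_m < px:
        raise ValueError(
            f"tile_size_m ({tile_size_m}) must be at least one pixel ({px})")
    tile_px = tile_size_m / px
    row_edges = _tile_edges(dsm.shape[0], tile_px)
    col_edges = _tile_edges(dsm.shape[1], tile_px)
    tiles: list[Tile] = []
    for ti in range(len(row_edges) - 1):
        for tj in range(len(col_edges) - 1):
            tiles.append(Tile(
                row_start=row_edges[ti], row_stop=row_edges[ti + 1],
                col_start=col_edges[tj], col_stop=col_edges[tj + 1],
                tile_row=ti, tile_col=tj,
            ))
    return tiles


def coarse_classify(tiles: Sequence[Tile], dsm: DsmGrid,
                    sd_threshold_m: float = 0.10) -> list[Tile]:
    """Label tiles tree/bare-soil by DSM height variability.

    A tile is a tree tile iff its population SD is *strictly* greater than
    ``sd_threshold_m``.  Nodata pixels are excluded; an all-nodata tile is
    bare soil.  Tiles are modified in place and returned.
    """
    elev = dsm.elevations
    valid = ~dsm.nodata_mask
    for tile in tiles:
        win = tile.window
        vals = elev[win][valid[win]]
        if vals.size == 0:
            tile.sd_dsm = None
            tile.label = "bare_soil"
            continue
        tile.sd_dsm = float(np.std(vals))  # population SD (divide by N)
        tile.label = "tree" if tile.sd_dsm > sd_threshold_m else "bare_soil"
    return list(tiles)


def nearest_mean_is_tree(value: float, mu_tree: float | None,
                         mu_soil: float | None) -> bool:
    """Nearest-class-mean border rule; ties and missing tree mean go to soil."""
    if mu_tree is None:
        return False
    if mu_soil is None:
        return True
    return abs(value - mu_tree) < abs(value - mu_soil)


def _disk_kernel(radius_px: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius_px:radius_px + 1, -radius_px:radius_px + 1]
    return (xx * xx + yy * yy <= radius_px * radius_px).astype(np.float64)


def _local_mean(values: np.ndarray, mask: np.ndarray, kernel: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Windowed mean of ``values`` over ``mask``; returns (mean, has_data)."""
    m = mask.astype(np.float64)
    sums = fftconvolve(values * m, kernel, mode="same")
    counts = fftconvolve(m, kernel, mode="same")
    has = counts > 0.5
    mean = np.zeros_like(sums)
    np.divide(sums, counts, out=mean, where=has)
    return mean, has


def _soil_surface(elev: np.ndarray, soil_mask: np.ndarray, pixel_size: float,
                  smooth_m: float = 1.0) -> tuple[np.ndarray, float]:
    """Estimate the bare-soil elevation surface under the whole raster.

    Every pixel takes the elevation of its nearest soil-reference pixel
    (Euclidean), then the filled surface is Gaussian-smoothed.  Returns the
    surface and the SD of its residuals on the soil pixels themselves, a
    measure of how well it tracks terrain roughness and DSM noise.
    """
    _, (ir, ic) = ndimage.distance_transform_edt(~soil_mask, return_indices=True)
    surface = elev[ir, ic]
    sigma_px = max(1.0, smooth_m / pixel_size / 2.0)
    surface = ndimage.gaussian_filter(surface, sigma=sigma_px)
    residual_sd = float(np.std(elev[soil_mask] - surface[soil_mask]))
    return surface, residual_sd


def _tile_label_grid(tiles: Sequence[Tile]) -> np.ndarray:
    n_tr = max(t.tile_row for t in tiles) + 1
    n_tc = max(t.tile_col for t in tiles) + 1
    grid = np.full((n_tr, n_tc), "", dtype=object)
    for t in tiles:
        grid[t.tile_row, t.tile_col] = t.label
    return grid


def refine_borders(tiles: Sequence[Tile], dsm: DsmGrid,
                   window_radius_m: float = 1.5,
                   rule: str = "height-above-soil",
                   soil_margin_m: float = 0.10,
                   min_tree_area_m2: float = 0.5,
                   include_soil_side: bool = True,
                   refine_all_tree_tiles: bool | None = None) -> TreeMask:
    """Pixel-level refinement of tree borders and individual-tree labeling.

    Under the default rule every tree tile is refined (``refine_all_tree_tiles``
    defaults to True there): in dense plantations a tile wedged between two
    crowns touches no soil tile at all, yet its soil pixels must not weld the
    crowns together.  The height-above-soil test leaves genuine canopy pixels
    untouched, so refining interior tiles is safe.  The nearest-mean rule
    needs interior tree tiles as its tree reference, so there only interface
    tiles are refined.
    """
    if rule not in ("height-above-soil", "nearest-mean"):
        raise ValueError(f"unknown border rule {rule!r}")
    if refine_all_tree_tiles is None:
        refine_all_tree_tiles = rule == "height-above-soil"
    elev = dsm.elevations
    valid = ~dsm.nodata_mask
    shape = dsm.shape

    grid = _tile_label_grid(tiles)
    tree_grid = grid == "tree"
    soil_grid = grid == "bare_soil"
    if not tree_grid.any():
        return TreeMask(labels=np.zeros(shape, dtype=np.int32), n_trees=0,
                        transform=dsm.transform, crs_label=dsm.crs_label)

    four = ndimage.generate_binary_structure(2, 1)
    soil_neighbour = ndimage.binary_dilation(soil_grid, structure=four)
    tree_neighbour = ndimage.binary_dilation(tree_grid, structure=four)
    border_grid = tree_grid if refine_all_tree_tiles else (tree_grid & soil_neighbour)
    if include_soil_side:
        border_grid |= soil_grid & tree_neighbour

    tree_px = np.zeros(shape, dtype=bool)
    border_px = np.zeros(shape, dtype=bool)
    soil_ref_px = np.zeros(shape, dtype=bool)
    for t in tiles:
        win = t.window
        if border_grid[t.tile_row, t.tile_col]:
            border_px[win] = True
        elif t.label == "tree":
            tree_px[win] = True
        else:
            soil_ref_px[win] = True
    tree_px &= valid
    border_px &= valid
    soil_ref_px &= valid

    px = dsm.pixel_size
    radius_px = max(1, int(round(window_radius_m / px)))

    if rule == "height-above-soil":
        if soil_ref_px.any():
            soil_surface, residual_sd = _soil_surface(elev, soil_ref_px, px)
            # margin adapts to how well the soil surface tracks the terrain
            # (roughness, DSM noise): 3 sigma of the soil-pixel residuals
            margin = max(soil_margin_m, 3.0 * residual_sd)
            assigned = elev - soil_surface > margin
        else:
            assigned = np.ones(shape, dtype=bool)  # no soil anywhere
    else:  # nearest-mean
        kernel = _disk_kernel(radius_px)
        mu_soil, has_soil = _local_mean(elev, soil_ref_px, kernel)
        if (border_px.any() and not (has_soil | ~border_px).all()
                and soil_ref_px.any()):
            # widen the window where no soil reference was in reach
            wide = _disk_kernel(radius_px * 3)
            mu_soil_w, has_soil_w = _local_mean(elev, soil_ref_px, wide)
            fill = border_px & ~has_soil & has_soil_w
            mu_soil[fill] = mu_soil_w[fill]
            has_soil |= has_soil_w
        mu_tree, has_tree = _local_mean(elev, tree_px, kernel)
        d_tree = np.abs(elev - mu_tree)
        d_soil = np.abs(elev - mu_soil)
        assigned = has_tree & (~has_soil | (d_tree < d_soil))

    final_tree = tree_px | (border_px & assigned)

    eight = ndimage.generate_binary_structure(2, 2)
    labels, n = ndimage.label(final_tree, structure=eight)
    if n:
        min_pixels = max(1, int(round(min_tree_area_m2 / dsm.pixel_area)))
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts >= min_pixels)
        keep = keep[keep > 0]
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
        labels = remap[labels]
        n = int(keep.size)
    return TreeMask(labels=labels.astype(np.int32), n_trees=int(n),
                    transform=dsm.transform, crs_label=dsm.crs_label)


def _watershed_split(mask: TreeMask, dsm: DsmGrid, config: OrchardConfig) -> TreeMask:
    """Split merged components with watershed seeded at plantation grid nodes."""
    from skimage.segmentation import watershed

    markers = np.zeros(mask.labels.shape, dtype=np.int32)
    rows = np.repeat(np.arange(1, config.n_rows + 1), config.n_cols)
    cols = np.tile(np.arange(1, config.n_cols + 1), config.n_rows)
    xs, ys = config.node_xy(rows, cols)
    rr, cc = mask.transform.rowcol(xs, ys)
    inside = (rr >= 0) & (rr < markers.shape[0]) & (cc >= 0) & (cc < markers.shape[1])
    markers[rr[inside], cc[inside]] = np.arange(1, inside.sum() + 1)
    tree = mask.labels > 0
    markers[~tree] = 0
    if not markers.any():
        return mask
    split = watershed(-dsm.elevations, markers=markers, mask=tree)
    # pixels of components that contain no marker keep their original label id
    orphan = tree & (split == 0)
    if orphan.any():
        split = np.where(orphan, mask.labels + split.max(), split)
    ids = np.unique(split)
    ids = ids[ids > 0]
    remap = np.zeros(split.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return TreeMask(labels=remap[split], n_trees=int(ids.size),
                    transform=mask.transform, crs_label=mask.crs_label)


def delineate(scene: MultiLayerScene | DsmGrid,
              params: DelineationParams | None = None,
              config: OrchardConfig | None = None) -> TreeMask:
    """Full delineation: segment -> classify -> refine -> label.

    Accepts a scene or a bare DSM.  ``config`` is only needed when
    ``params.split_merged`` is set (watershed markers at grid nodes).
    """
    params = params or DelineationParams()
    dsm = scene.dsm if isinstance(scene, MultiLayerScene) else scene
    tiles = chessboard_segment(dsm, params.tile_size_m)
    tiles = coarse_classify(tiles, dsm, params.sd_threshold_m)
    mask = refine_borders(
        tiles, dsm,
        window_radius_m=params.window_radius_m, rule=params.rule,
        soil_margin_m=params.soil_margin_m,
        min_tree_area_m2=params.min_tree_area_m2,
        include_soil_side=params.include_soil_side)
    if params.split_merged:
        if config is None:
            raise ValueError("split_merged requires an OrchardConfig")
        mask = _watershed_split(mask, dsm, config)
    return mask
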