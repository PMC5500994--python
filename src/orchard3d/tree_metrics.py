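"""Per-tree geometric features from a labeled crown mask and a DSM.

For every delineated tree the pipeline computes:

* *ground reference* — the mean DSM elevation of bare-soil pixels in a ring
  (default 1 m wide) around the crown; a single per-tree constant, kept even
  on sloped terrain.
* *height* — maximum DSM value over the crown minus the ground reference.
* *projected canopy area* — pixel count times pixel area.
* *crown volume* — per-pixel (DSM - ground reference) clamped at zero, times
  pixel area, summed over the crown.
* *grid identity* — the (row, column) plantation position, from the centroid
  rotated into plantation axes and rounded to the nearest node; the pruning
  treatment follows from the row's treatment block.

Trees whose ring contains no bare soil out to 3 m are "landlocked", trees with
non-positive height or an excessive nodata share are flagged unreliable; all
flagged trees are excluded from downstream change statistics but still
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .obia_delineation import TreeMask
from .raster_model import DsmGrid, MultiLayerScene, OrchardConfig

__all__ = [
    "TreeObject",
    "TreeRecord",
    "LandlockedTreeError",
    "compute_ground_reference",
    "compute_height",
    "compute_area",
    "compute_volume",
    "assign_grid_position",
    "extract_features",
]


class LandlockedTreeError(RuntimeError):
    """No bare soil found within the maximum search buffer around a tree."""


@dataclass
class TreeObject:
    """A delineated crown: pixel support plus derived features."""

    tree_id: int
    rows: np.ndarray  # pixel indices of the crown
    cols: np.ndarray
    bbox: tuple[int, int, int, int]  # row0, row1, col0, col1 (exclusive)
    centroid_xy: tuple[float, float] = (0.0, 0.0)
    ground_ref_elev: float = float("nan")
    area_m2: float = 0.0
    height_m: float = 0.0
    volume_m3: float = 0.0
    row: int = 0
    column: int = 0
    treatment: str = ""
    reliable: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def n_pixels(self) -> int:
        return int(self.rows.size)

    def flag(self, reason: str) -> None:
        self.reliable = False
        if reason not in self.flags:
            self.flags.append(reason)


@dataclass
class TreeRecord:
    """One output row per tree per date (vector/table export schema)."""

    tree_id: int
    row: int
    column: int
    x: float
    y: float
    treatment: str
    date_label: str
    area_m2: float
    height_m: float
    volume_m3: float
    reliable: bool = True
    flags: tuple[str, ...] = ()
    geometry: object | None = None  # shapely Polygon, optional
    crs_label: str = ""


def _tree_objects(mask: TreeMask) -> list[TreeObject]:
    labels = mask.labels
    objects = ndimage.find_objects(labels)
    trees: list[TreeObject] = []
    for tree_id in range(1, mask.n_trees + 1):
        sl = objects[tree_id - 1]
        if sl is None:
            continue
        local = labels[sl] == tree_id
        rr, cc = np.nonzero(local)
        trees.append(TreeObject(
            tree_id=tree_id,
            rows=rr + sl[0].start, cols=cc + sl[1].start,
            bbox=(sl[0].start, sl[0].stop, sl[1].start, sl[1].stop),
        ))
    return trees


def compute_ground_reference(tree: TreeObject, mask: TreeMask, dsm: DsmGrid,
                             buffer_m: float = 1.0,
                             max_buffer_m: float = 3.0,
                             widen_step_m: float = 0.5) -> float:
    """Mean bare-soil DSM elevation in a ring around the tree.

    The ring extends ``buffer_m`` outward from the crown boundary (Euclidean
    distance); pixels belonging to any tree or flagged nodata are excluded.
    If no soil pixel is found, the ring widens by ``widen_step_m`` up to
    ``max_buffer_m`` before raising :class:`LandlockedTreeError`.
    """
    if tree.n_pixels == 0:
        raise ValueError("tree has no pixels")
    px = dsm.pixel_size
    pad = int(math.ceil(max_buffer_m / px)) + 1
    r0 = max(0, tree.bbox[0] - pad)
    r1 = min(dsm.shape[0], tree.bbox[1] + pad)
    c0 = max(0, tree.bbox[2] - pad)
    c1 = min(dsm.shape[1], tree.bbox[3] + pad)
    window = (slice(r0, r1), slice(c0, c1))
    component = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    component[tree.rows - r0, tree.cols - c0] = True
    dist_m = ndimage.distance_transform_edt(~component) * px
    soil = (mask.labels[window] == 0) & ~dsm.nodata_mask[window]
    elev = dsm.elevations[window]
    b = buffer_m
    while b <= max_buffer_m + 1e-9:
        ring = soil & (dist_m <= b)
        if ring.any():
            return float(elev[ring].mean())
        b += widen_step_m
    raise LandlockedTreeError(
        f"tree {tree.tree_id}: no bare soil within {max_buffer_m} m")


def compute_height(tree: TreeObject, dsm: DsmGrid, ground_ref: float,
                   height_quantile: float = 1.0) -> float:
    """Tree height: maximum crown DSM value minus the ground reference.

    ``height_quantile`` < 1 substitutes an upper quantile of the crown DSM for
    the raw maximum (robustification for noisy DSMs; default is the maximum).
    """
    vals = dsm.elevations[tree.rows, tree.cols]
    vals = vals[~dsm.nodata_mask[tree.rows, tree.cols]]
    if vals.size == 0:
        return float("nan")
    top = float(vals.max()) if height_quantile >= 1.0 else float(
        np.quantile(vals, height_quantile))
    return top - ground_ref


def compute_area(tree: TreeObject, pixel_size: float) -> float:
    """Projected canopy area: pixel count times pixel area."""
    return tree.n_pixels * pixel_size ** 2


def compute_volume(tree: TreeObject, dsm: DsmGrid, ground_ref: float,
                   pixel_size: float) -> float:
    """Crown volume: sum of per-pixel heights (clamped at 0) times pixel area."""
    vals = dsm.elevations[tree.rows, tree.cols]
    good = ~dsm.nodata_mask[tree.rows, tree.cols]
    heights = np.clip(vals[good] - ground_ref, 0.0, None)
    return float(heights.sum() * pixel_size ** 2)


def assign_grid_position(trees: Sequence[TreeObject], config: OrchardConfig
                         ) -> list[TreeObject]:
    """Snap each tree's centroid to the nearest plantation grid node.

    Centroids are transformed into fractional (row, column) coordinates and
    rounded; results are clipped to the grid.  A centroid farther than half a
    spacing from its node is flagged ``off-grid``.  When two trees snap to one
    node the nearer centroid keeps it and the other is flagged unreliable.
    Treatments are assigned from the config's row blocks.
    """
    claimed: dict[tuple[int, int], tuple[float, TreeObject]] = {}
    for tree in trees:
        fr, fc = config.grid_coords(*tree.centroid_xy)
        fr, fc = float(fr), float(fc)
        row = int(round(fr))
        col = int(round(fc))
        off = (abs(fr - row) > 0.5 + 1e-9) or (abs(fc - col) > 0.5 + 1e-9)
        row_clipped = min(max(row, 1), config.n_rows)
        col_clipped = min(max(col, 1), config.n_cols)
        if (row_clipped, col_clipped) != (row, col):
            off = True
        tree.row, tree.column = row_clipped, col_clipped
        if off:
            tree.flag("off-grid")
        tree.treatment = config.treatment_for_row(tree.row)
        nx, ny = config.node_xy(tree.row, tree.column)
        d = math.hypot(tree.centroid_xy[0] - float(nx),
                       tree.centroid_xy[1] - float(ny))
        key = (tree.row, tree.column)
        if key in claimed:
            d_prev, prev = claimed[key]
            if d < d_prev:
                prev.flag("duplicate-node")
                claimed[key] = (d, tree)
            else:
                tree.flag("duplicate-node")
        else:
            claimed[key] = (d, tree)
    return list(trees)


def _crown_polygon(tree: TreeObject, mask: TreeMask):
    """Outline polygon of the crown component in map coordinates."""
    from shapely.geometry import Polygon
    from skimage.measure import find_contours

    r0, r1, c0, c1 = tree.bbox
    local = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=float)
    local[tree.rows - r0 + 1, tree.cols - c0 + 1] = 1.0
    contours = find_contours(local, 0.5)
    if not contours:
        return None
    outline = max(contours, key=len)
    rows = outline[:, 0] - 1 + r0
    cols = outline[:, 1] - 1 + c0
    xs, ys = mask.transform.xy(rows, cols)
    poly = Polygon(np.column_stack([xs, ys]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def extract_features(mask: TreeMask, scene: MultiLayerScene | DsmGrid,
                     config: OrchardConfig | None = None,
                     buffer_m: float = 1.0,
                     max_nodata_fraction: float = 0.2,
                     height_quantile: float = 1.0,
                     with_geometry: bool = True) -> list[TreeRecord]:
    """Loop over every labeled tree and compute its full feature record.

    Records are sorted by (row, column) when a plantation config is given,
    else by tree id.  An empty mask yields an empty list.
    """
    dsm = scene.dsm if isinstance(scene, MultiLayerScene) else scene
    date_label = scene.date_label if isinstance(scene, MultiLayerScene) else ""
    trees = _tree_objects(mask)
    px = dsm.pixel_size
    for tree in trees:
        xs, ys = mask.transform.xy(tree.rows, tree.cols)
        tree.centroid_xy = (float(xs.mean()), float(ys.mean()))
        tree.area_m2 = compute_area(tree, px)
        try:
            tree.ground_ref_elev = compute_ground_reference(
                tree, mask, dsm, buffer_m=buffer_m)
        except LandlockedTreeError:
            tree.flag("landlocked")
            tree.ground_ref_elev = float("nan")
        if math.isfinite(tree.ground_ref_elev):
            tree.height_m = compute_height(tree, dsm, tree.ground_ref_elev,
                                           height_quantile=height_quantile)
            tree.volume_m3 = compute_volume(tree, dsm, tree.ground_ref_elev, px)
            if not tree.height_m > 0:
                tree.flag("non-positive-height")
        # nodata share within the filled crown footprint
        r0, r1, c0, c1 = tree.bbox
        footprint = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        footprint[tree.rows - r0, tree.cols - c0] = True
        footprint = ndimage.binary_fill_holes(footprint)
        nodata = dsm.nodata_mask[r0:r1, c0:c1] & footprint
        if footprint.sum() and nodata.sum() / footprint.sum() > max_nodata_fraction:
            tree.flag("excess-nodata")

    if config is not None:
        assign_grid_position(trees, config)
        trees.sort(key=lambda t: (t.row, t.column, t.tree_id))
    records = []
    for tree in trees:
        geometry = _crown_polygon(tree, mask) if with_geometry else None
        records.append(TreeRecord(
            tree_id=tree.tree_id, row=tree.row, column=tree.column,
            x=tree.centroid_xy[0], y=tree.centroid_xy[1],
            treatment=tree.treatment, date_label=date_label,
            area_m2=tree.area_m2, height_m=tree.height_m,
            volume_m3=tree.volume_m3, reliable=tree.reliable,
            flags=tuple(tree.flags), geometry=geometry,
            crs_label=mask.crs_label,
        ))
    return records
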