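"""Synthetic multi-date orchard DSM scenes with exact ground truth.

Real UAV photogrammetry of the study system (an intensively planted olive
orchard, 27 x 24 trees at 8 x 4 m spacing) is emulated by parametric crowns on
smooth terrain.  Crowns are half-ellipsoids raised on a trunk: the canopy base
sits ``crown_base_height`` above the ground (olive canopies are kept ~60 cm
over the soil) and the visible canopy top is the upper ellipsoid sheet.  A DSM
looks at the canopy *from above*, so the surface it records over a crown's
footprint is

    z(x, y) = h0 + c * sqrt(1 - (x/a)^2 - (y/b)^2)

with ``h0`` the crown base height, ``c = apex - h0`` the vertical semi-axis and
``a, b`` the horizontal semi-axes.  The volume a DSM-based pipeline measures is
the integral of that surface over the footprint (it cannot see under-canopy
gaps), and that integral has a closed form, which doubles as the ground-truth
oracle:

    V = pi*a*b * [ h0*(1 - u_l^2) + (2c/3)*(1 - u_l^3) ]
        - pi*a*b*c * (2 - 3*u_t + u_t^3) / 3

where ``u_l = (skirt - h0)/c`` accounts for a raised skirt (mechanical low
cut) and ``u_t = (top_cut - h0)/c`` for a flattened top (mechanical topping);
both clamp to [0, 1] and are 0 / 1 respectively when no cut applies, which
reduces to the familiar half-ellipsoid volume ``(2/3)*pi*a*b*c + pi*a*b*h0``.

Three pruning treatments are simulated:

* ``traditional`` — removes a fraction of the crown volume by shrinking the
  horizontal semi-axes (volume is proportional to a*b, so the factor is
  ``sqrt(1 - f)``).
* ``adapted`` — same mechanism with a typically larger fraction, plus an
  optional central-core gap; the gap is mostly invisible to a surface DSM and
  only alters the rendered surface where it breaches the canopy top.
* ``mechanical`` — tractor topping: the canopy is clamped at a cut height
  (uniform in 3.5-4.0 m above the terrain) and a low horizontal cut removes
  branches below 0.7 m.

Regrowth after pruning is horizontal (olives regrow along the horizontal axes
after pruning, not upward): semi-axes scale by ``sqrt(1 + g)`` where ``g`` is
looked up from the tree's own pruning-severity class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .raster_model import DsmGrid, GridTransform, MultiLayerScene, OrchardConfig

__all__ = [
    "CrownModel",
    "CrownParams",
    "PruningSpec",
    "TreeTruth",
    "OrchardTruth",
    "DEFAULT_GROWTH_BY_SEVERITY",
    "generate_terrain",
    "generate_orchard",
    "render_dsm",
    "apply_pruning",
    "apply_regrowth",
    "truth_from_crowns",
    "field_extent",
    "simulate_field",
    "inject_reconstruction_artifacts",
]

TREATMENTS = ("traditional", "adapted", "mechanical")

#: Default fractional annual volume growth per pruning-severity class
#: (percent of crown volume removed).  Severely pruned trees regrow more.
DEFAULT_GROWTH_BY_SEVERITY: dict[str, float] = {
    "<10%": 0.25,
    "10-30%": 0.35,
    "30-50%": 0.60,
    ">50%": 0.80,
}


def _severity_class(severity_pct: float) -> str:
    """Severity class label for a percent crown-volume removal (left-closed)."""
    s = max(0.0, float(severity_pct))
    if s < 10.0:
        return "<10%"
    if s < 30.0:
        return "10-30%"
    if s < 50.0:
        return "30-50%"
    return ">50%"


@dataclass
class CrownModel:
    """A single half-ellipsoid crown, optionally topped and/or skirted."""

    center_xy: tuple[float, float]
    trunk_base_elev: float
    crown_base_height: float
    apex_height: float
    semi_axis_x: float
    semi_axis_y: float
    top_cut_height: float | None = None
    skirt_height: float | None = None
    core_gap_radius_m: float = 0.0
    core_gap_floor_height: float | None = None
    pruning_severity: float | None = None  # fraction of volume removed
    tree_id: int = 0
    row: int = 0
    column: int = 0
    treatment: str = ""

    def __post_init__(self) -> None:
        if not (self.apex_height > self.crown_base_height >= 0):
            raise ValueError("need apex_height > crown_base_height >= 0")
        if self.semi_axis_x <= 0 or self.semi_axis_y <= 0:
            raise ValueError("semi-axes must be positive")

    # -- geometry ----------------------------------------------------------

    @property
    def _c(self) -> float:
        return self.apex_height - self.crown_base_height

    @property
    def _u_low(self) -> float:
        if self.skirt_height is None:
            return 0.0
        return min(1.0, max(0.0, (self.skirt_height - self.crown_base_height) / self._c))

    @property
    def _u_top(self) -> float:
        if self.top_cut_height is None:
            return 1.0
        return min(1.0, max(0.0, (self.top_cut_height - self.crown_base_height) / self._c))

    @property
    def visible_height(self) -> float:
        """Ground-to-canopy-top height as seen by a DSM."""
        if self.top_cut_height is None:
            return self.apex_height
        return min(self.apex_height, self.top_cut_height)

    def projected_area(self) -> float:
        """Visible (vertically projected) footprint area, m^2."""
        return math.pi * self.semi_axis_x * self.semi_axis_y * (1.0 - self._u_low ** 2)

    def volume(self) -> float:
        """Exact DSM-visible crown volume (surface integral above ground), m^3."""
        a, b, c, h0 = self.semi_axis_x, self.semi_axis_y, self._c, self.crown_base_height
        ul, ut = self._u_low, self._u_top
        v = math.pi * a * b * (h0 * (1.0 - ul ** 2) + (2.0 * c / 3.0) * (1.0 - ul ** 3))
        v -= math.pi * a * b * c * (2.0 - 3.0 * ut + ut ** 3) / 3.0
        if self.core_gap_radius_m > 0 and self.core_gap_floor_height is not None:
            v = self._volume_numeric(resolution=0.01)
        return v

    def surface_height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Canopy-top height above ground at map coordinates; 0 outside."""
        dx = (np.asarray(x, dtype=float) - self.center_xy[0]) / self.semi_axis_x
        dy = (np.asarray(y, dtype=float) - self.center_xy[1]) / self.semi_axis_y
        rho2 = dx * dx + dy * dy
        sheet = self.crown_base_height + self._c * np.sqrt(np.clip(1.0 - rho2, 0.0, None))
        h = np.where(rho2 <= 1.0 - self._u_low ** 2, sheet, 0.0)
        if self.top_cut_height is not None:
            h = np.minimum(h, self.top_cut_height)
        if self.core_gap_radius_m > 0 and self.core_gap_floor_height is not None:
            r2 = ((np.asarray(x, dtype=float) - self.center_xy[0]) ** 2
                  + (np.asarray(y, dtype=float) - self.center_xy[1]) ** 2)
            in_core = r2 <= self.core_gap_radius_m ** 2
            h = np.where(in_core & (h > 0), np.minimum(h, self.core_gap_floor_height), h)
        return h

    def _volume_numeric(self, resolution: float = 0.01) -> float:
        """Brute-force surface integration; used when no closed form applies."""
        a = self.semi_axis_x
        b = self.semi_axis_y
        xs = np.arange(-a, a + resolution, resolution) + self.center_xy[0]
        ys = np.arange(-b, b + resolution, resolution) + self.center_xy[1]
        xx, yy = np.meshgrid(xs, ys)
        return float(self.surface_height(xx, yy).sum() * resolution ** 2)


@dataclass
class CrownParams:
    """Sampling distributions for crown dimensions.

    Defaults emulate mature intensively planted olives: apex heights around
    3.3-4.5 m and projected areas of roughly 7-14 m^2.  The within-row
    semi-axis (``semi_along``) is kept below half the 4 m tree spacing so
    neighbouring crowns stay separable; the across-row axis may be larger
    (rows are 8 m apart).
    """

    apex_height_mean: float = 4.0
    apex_height_sd: float = 0.25
    apex_height_range: tuple[float, float] = (3.3, 4.5)
    semi_along_range: tuple[float, float] = (1.35, 1.75)
    semi_across_range: tuple[float, float] = (1.6, 2.3)
    crown_base_height: float = 0.6


@dataclass
class PruningSpec:
    """One pruning treatment applied to a block of crowns.

    ``top_cut_height_m`` (mechanical) may be None, in which case each tree's
    cut height is drawn uniformly from 3.5-4.0 m above the terrain.
    ``volume_removal_fraction`` (traditional/adapted) is the fraction of the
    crown volume removed; ``fraction_sd`` adds per-tree normal spread
    (clipped to [0, 0.9]) for severity-class experiments.
    """

    treatment: str
    top_cut_height_m: float | None = None
    top_cut_range: tuple[float, float] = (3.5, 4.0)
    low_cut_height_m: float = 0.7
    volume_removal_fraction: float = 0.0
    fraction_sd: float = 0.0
    core_gap_radius_m: float = 0.0
    core_gap_depth_m: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if not (0.0 <= self.volume_removal_fraction < 1.0):
            raise ValueError("volume_removal_fraction must be in [0, 1)")
        if self.top_cut_height_m is not None and self.top_cut_height_m <= self.low_cut_height_m:
            raise ValueError("top cut must be above the low cut")


@dataclass
class TreeTruth:
    tree_id: int
    row: int
    column: int
    center_xy: tuple[float, float]
    true_height_m: float
    true_area_m2: float
    true_volume_m3: float
    treatment: str


@dataclass
class OrchardTruth:
    """Exact per-tree ground truth for one synthetic date."""

    trees: list[TreeTruth]
    date_label: str = ""

    def by_position(self) -> dict[tuple[int, int], TreeTruth]:
        return {(t.row, t.column): t for t in self.trees}


def truth_from_crowns(crowns: Sequence[CrownModel], date_label: str = "") -> OrchardTruth:
    trees = [
        TreeTruth(
            tree_id=c.tree_id, row=c.row, column=c.column, center_xy=c.center_xy,
            true_height_m=c.visible_height, true_area_m2=c.projected_area(),
            true_volume_m3=c.volume(), treatment=c.treatment,
        )
        for c in crowns
    ]
    return OrchardTruth(trees=trees, date_label=date_label)


# ---------------------------------------------------------------------------
# Terrain
# ---------------------------------------------------------------------------

def field_extent(config: OrchardConfig, margin_m: float = 6.0
                 ) -> tuple[float, float, float, float]:
    """(x_min, y_min, x_max, y_max) covering the grid plus a margin."""
    rows = np.array([1, 1, config.n_rows, config.n_rows])
    cols = np.array([1, config.n_cols, 1, config.n_cols])
    xs, ys = config.node_xy(rows, cols)
    return (float(xs.min() - margin_m), float(ys.min() - margin_m),
            float(xs.max() + margin_m), float(ys.max() + margin_m))


def generate_terrain(extent_m: tuple[float, float], pixel_size: float,
                     slope: tuple[float, float] = (0.0, 0.0),
                     roughness_sd: float = 0.0,
                     roughness_wavelength_m: float = 20.0, seed: int = 0,
                     origin_xy: tuple[float, float] = (0.0, 0.0),
                     base_elev: float = 100.0,
                     crs_label: str = "EPSG:32630",
                     config: OrchardConfig | None = None) -> DsmGrid:
    """Smooth terrain: a plane plus a low-frequency random field.

    ``extent_m`` is (width, height) in meters, anchored with its lower-left
    corner at ``origin_xy``.  ``slope`` is the (d elev/dx, d elev/dy) gradient;
    ``roughness_sd`` scales gentle undulations of ``roughness_wavelength_m``
    scale (default 20 m — a cultivated, deep-soil field undulates at tens of
    meters, not at the scale of a single crown).  If ``config`` is given, the
    extent must cover the plantation footprint plus a 5 m margin.
    """
    width, height = float(extent_m[0]), float(extent_m[1])
    if width <= 0 or height <= 0:
        raise ValueError("extent must be positive")
    if config is not None:
        x0, y0, x1, y1 = field_extent(config, margin_m=5.0)
        if (origin_xy[0] > x0 or origin_xy[1] > y0
                or origin_xy[0] + width < x1 or origin_xy[1] + height < y1):
            raise ValueError(
                "terrain extent does not cover the plantation footprint plus a 5 m margin")
    n_cols = max(1, int(round(width / pixel_size)))
    n_rows = max(1, int(round(height / pixel_size)))
    transform = GridTransform(x_min=origin_xy[0],
                              y_max=origin_xy[1] + n_rows * pixel_size,
                              pixel_size=pixel_size)
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    xs, ys = transform.xy(rr, cc)
    elev = base_elev + slope[0] * (xs - origin_xy[0]) + slope[1] * (ys - origin_xy[1])
    if roughness_sd > 0:
        rng = np.random.default_rng(seed)
        wavelength = roughness_wavelength_m
        coarse_shape = (max(2, int(n_rows * pixel_size / wavelength) + 2),
                        max(2, int(n_cols * pixel_size / wavelength) + 2))
        coarse = rng.normal(0.0, roughness_sd, size=coarse_shape)
        zoom = (n_rows / coarse_shape[0], n_cols / coarse_shape[1])
        elev = elev + ndimage.zoom(coarse, zoom, order=3)[:n_rows, :n_cols]
    return DsmGrid(elevations=elev, transform=transform, crs_label=crs_label)


# ---------------------------------------------------------------------------
# Orchard generation
# ---------------------------------------------------------------------------

def _ellipse_radius_along(a: float, b: float, ux: float, uy: float) -> float:
    """Radius of an axis-aligned ellipse along unit direction (ux, uy)."""
    return 1.0 / math.sqrt((ux / a) ** 2 + (uy / b) ** 2)


def _check_overlap(crowns: Sequence[CrownModel], config: OrchardConfig) -> None:
    by_pos = {(c.row, c.column): c for c in crowns}
    for c in crowns:
        for dr, dc in ((0, 1), (1, 0)):
            other = by_pos.get((c.row + dr, c.column + dc))
            if other is None:
                continue
            dx = other.center_xy[0] - c.center_xy[0]
            dy = other.center_xy[1] - c.center_xy[1]
            d = math.hypot(dx, dy)
            ux, uy = dx / d, dy / d
            r1 = _ellipse_radius_along(c.semi_axis_x, c.semi_axis_y, ux, uy)
            r2 = _ellipse_radius_along(other.semi_axis_x, other.semi_axis_y, ux, uy)
            if r1 + r2 >= d:
                raise ValueError(
                    f"crowns at grid ({c.row},{c.column}) and "
                    f"({other.row},{other.column}) overlap; "
                    "reduce semi-axes/jitter or pass allow_overlap=True")


def generate_orchard(config: OrchardConfig,
                     crown_params: CrownParams | None = None,
                     jitter_sd: float = 0.1, seed: int = 0,
                     allow_overlap: bool = False,
                     terrain: DsmGrid | None = None,
                     date_label: str = "Date 1",
                     ) -> tuple[list[CrownModel], OrchardTruth]:
    """One crown per grid node, with jittered centers and exact analytic truth.

    Center jitter is truncated Normal(0, jitter_sd^2), clipped at 2 sigma per
    axis so the overlap guarantee stays deterministic.  ``trunk_base_elev`` is
    taken from ``terrain`` at each center (0 if no terrain is given).
    """
    params = crown_params or CrownParams()
    rng = np.random.default_rng(seed)
    crowns: list[CrownModel] = []
    u, v = config.axes()
    tree_id = 0
    for row in range(1, config.n_rows + 1):
        for col in range(1, config.n_cols + 1):
            tree_id += 1
            x, y = config.node_xy(row, col)
            if jitter_sd > 0:
                jx, jy = np.clip(rng.normal(0.0, jitter_sd, size=2),
                                 -2 * jitter_sd, 2 * jitter_sd)
            else:
                jx = jy = 0.0
            cx, cy = float(x + jx), float(y + jy)
            apex = float(np.clip(rng.normal(params.apex_height_mean, params.apex_height_sd),
                                 *params.apex_height_range))
            semi_along = float(rng.uniform(*params.semi_along_range))
            semi_across = float(rng.uniform(*params.semi_across_range))
            # ellipse axes follow the plantation axes: along-row axis = u
            semi_x = math.hypot(semi_along * u[0], semi_across * v[0])
            semi_y = math.hypot(semi_along * u[1], semi_across * v[1])
            if abs(config.row_azimuth_deg % 90.0) > 1e-9:
                # crowns are axis-aligned ellipses; for rotated plantations use
                # the bounding isotropic radius to stay conservative
                semi_x = semi_y = min(semi_along, semi_across)
            base_elev = 0.0
            if terrain is not None:
                r, c = terrain.transform.rowcol(cx, cy)
                r = int(np.clip(r, 0, terrain.shape[0] - 1))
                c = int(np.clip(c, 0, terrain.shape[1] - 1))
                base_elev = float(terrain.elevations[r, c])
            crowns.append(CrownModel(
                center_xy=(cx, cy), trunk_base_elev=base_elev,
                crown_base_height=params.crown_base_height, apex_height=apex,
                semi_axis_x=semi_x, semi_axis_y=semi_y,
                tree_id=tree_id, row=row, column=col,
                treatment=config.treatment_for_row(row),
            ))
    if not allow_overlap:
        _check_overlap(crowns, config)
    return crowns, truth_from_crowns(crowns, date_label)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_dsm(terrain: DsmGrid, crowns: Sequence[CrownModel],
               noise_sd: float = 0.0, seed: int = 0) -> DsmGrid:
    """Render crowns onto terrain as an opaque-from-above canopy DSM.

    Each pixel takes ``max(terrain, trunk_base_elev + crown surface height)``
    over all crowns covering it, then optional additive Gaussian noise.
    """
    out = terrain.elevations.copy()
    transform = terrain.transform
    n_rows, n_cols = terrain.shape
    px = transform.pixel_size
    for crown in crowns:
        cx, cy = crown.center_xy
        rx = crown.semi_axis_x + px
        ry = crown.semi_axis_y + px
        r0, c0 = transform.rowcol(cx - rx, cy + ry)
        r1, c1 = transform.rowcol(cx + rx, cy - ry)
        r0 = max(0, int(r0)); c0 = max(0, int(c0))
        r1 = min(n_rows - 1, int(r1)); c1 = min(n_cols - 1, int(c1))
        if r1 < r0 or c1 < c0:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1),
                             indexing="ij")
        xs, ys = transform.xy(rr, cc)
        h = crown.surface_height(xs, ys)
        crown_elev = np.where(h > 0, crown.trunk_base_elev + h, -np.inf)
        window = out[r0:r1 + 1, c0:c1 + 1]
        np.maximum(window, crown_elev, out=window)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return DsmGrid(elevations=out, transform=transform,
                   nodata_mask=terrain.nodata_mask.copy(),
                   crs_label=terrain.crs_label)


# ---------------------------------------------------------------------------
# Pruning and regrowth
# ---------------------------------------------------------------------------

def apply_pruning(crowns: Sequence[CrownModel], spec: PruningSpec,
                  date_label: str = "Date 2",
                  min_semi_axis: float = 0.05,
                  ) -> tuple[list[CrownModel], OrchardTruth]:
    """Apply one pruning treatment, recording each tree's actual severity.

    Mechanical: canopy clamped at the top-cut height (drawn per tree from
    ``top_cut_range`` when not fixed) and skirted at the low cut; truth volume
    is the exact truncated-ellipsoid integral.  Traditional/adapted: horizontal
    semi-axes scaled by ``sqrt(1 - f)``, which removes exactly fraction ``f``
    of the DSM-visible volume.
    """
    rng = np.random.default_rng(spec.seed)
    pruned: list[CrownModel] = []
    for crown in crowns:
        v_before = crown.volume()
        if spec.treatment == "mechanical":
            if spec.top_cut_height_m is not None:
                top = spec.top_cut_height_m
            else:
                top = float(rng.uniform(*spec.top_cut_range))
            new = replace(
                crown,
                top_cut_height=top,
                skirt_height=max(spec.low_cut_height_m,
                                 crown.skirt_height or crown.crown_base_height),
            )
        else:
            f = spec.volume_removal_fraction
            if spec.fraction_sd > 0:
                f = float(np.clip(rng.normal(f, spec.fraction_sd), 0.0, 0.9))
            scale = math.sqrt(1.0 - f)
            ax, ay = crown.semi_axis_x * scale, crown.semi_axis_y * scale
            if min(ax, ay) < min_semi_axis:
                raise ValueError(
                    f"removal fraction {f:.2f} drives tree {crown.tree_id} "
                    f"semi-axes below {min_semi_axis} m")
            new = replace(crown, semi_axis_x=ax, semi_axis_y=ay)
            if spec.treatment == "adapted" and spec.core_gap_radius_m > 0:
                new = replace(
                    new,
                    core_gap_radius_m=spec.core_gap_radius_m,
                    core_gap_floor_height=max(
                        new.crown_base_height + 1e-6,
                        new.visible_height - spec.core_gap_depth_m),
                )
        v_after = new.volume()
        severity = max(0.0, 1.0 - v_after / v_before) if v_before > 0 else 0.0
        new = replace(new, pruning_severity=severity)
        pruned.append(new)
    return pruned, truth_from_crowns(pruned, date_label)


def apply_regrowth(crowns: Sequence[CrownModel],
                   growth_fraction_by_severity: Mapping[str, float] | None = None,
                   seed: int = 0, noise_cv: float = 0.0,
                   ) -> list[CrownModel]:
    """Grow each crown horizontally by its severity class's volume fraction.

    ``growth_fraction_by_severity`` maps class labels (``"<10%"``, ``"10-30%"``,
    ``"30-50%"``, ``">50%"``) to fractional volume growth.  Per-tree lognormal
    multiplicative noise of coefficient of variation ``noise_cv`` is applied to
    the growth fraction.  Apex height is unchanged (horizontal regrowth).
    """
    lookup = dict(DEFAULT_GROWTH_BY_SEVERITY)
    if growth_fraction_by_severity is not None:
        lookup.update(growth_fraction_by_severity)
    for label, g in lookup.items():
        if g < 0:
            raise ValueError(f"negative growth fraction for class {label!r}")
    rng = np.random.default_rng(seed)
    grown: list[CrownModel] = []
    for crown in crowns:
        severity_pct = 100.0 * (crown.pruning_severity or 0.0)
        g = lookup[_severity_class(severity_pct)]
        if noise_cv > 0 and g > 0:
            sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
            g = g * float(rng.lognormal(-sigma ** 2 / 2.0, sigma))
        scale = math.sqrt(1.0 + g)
        grown.append(replace(crown, semi_axis_x=crown.semi_axis_x * scale,
                             semi_axis_y=crown.semi_axis_y * scale))
    return grown


# ---------------------------------------------------------------------------
# Optional reconstruction-artifact injector (off by default)
# ---------------------------------------------------------------------------

def inject_reconstruction_artifacts(dsm: DsmGrid, crowns: Sequence[CrownModel],
                                    deletion_fraction: float = 0.05,
                                    spike_fraction: float = 0.02,
                                    spike_height_m: float = 2.0,
                                    seed: int = 0) -> DsmGrid:
    """Emulate photogrammetric failures: flatten some crowns, spike some pixels.

    A stand-in for structure-from-motion reconstruction errors; purely for
    robustness experiments, never used in default pipelines.
    """
    rng = np.random.default_rng(seed)
    out = dsm.elevations.copy()
    transform = dsm.transform
    for crown in crowns:
        if rng.random() >= deletion_fraction:
            continue
        cx, cy = crown.center_xy
        rx, ry = crown.semi_axis_x, crown.semi_axis_y
        r0, c0 = transform.rowcol(cx - rx, cy + ry)
        r1, c1 = transform.rowcol(cx + rx, cy - ry)
        r0 = max(0, int(r0)); c0 = max(0, int(c0))
        r1 = min(dsm.shape[0] - 1, int(r1)); c1 = min(dsm.shape[1] - 1, int(c1))
        out[r0:r1 + 1, c0:c1 + 1] = crown.trunk_base_elev
    n_spikes = int(spike_fraction / 100.0 * out.size)
    if n_spikes > 0:
        rr = rng.integers(0, out.shape[0], n_spikes)
        cc = rng.integers(0, out.shape[1], n_spikes)
        out[rr, cc] += rng.uniform(0.5, spike_height_m, n_spikes)
    return DsmGrid(elevations=out, transform=transform,
                   nodata_mask=dsm.nodata_mask.copy(), crs_label=dsm.crs_label)


# ---------------------------------------------------------------------------
# Convenience: full three-date simulation
# ---------------------------------------------------------------------------

def simulate_field(config: OrchardConfig | None = None,
                   pixel_size: float = 0.05,
                   noise_sd: float = 0.0,
                   seed: int = 0,
                   crown_params: CrownParams | None = None,
                   jitter_sd: float = 0.1,
                   terrain_slope: tuple[float, float] = (0.0, 0.005),
                   terrain_roughness_sd: float = 0.05,
                   pruning_specs: Mapping[str, PruningSpec] | None = None,
                   growth_fraction_by_severity: Mapping[str, float] | None = None,
                   growth_noise_cv: float = 0.0,
                   dates: Sequence[str] = ("Date 1", "Date 2", "Date 3"),
                   ) -> dict[str, tuple[MultiLayerScene, OrchardTruth]]:
    """Simulate the three-date study: before pruning, after, one year after.

    Each treatment block receives its own :class:`PruningSpec`; defaults are a
    36% volume removal (traditional), 42% (adapted) and mechanical topping,
    matching the character of the three field treatments.  Returns
    ``{date_label: (scene, truth)}``.
    """
    config = config or OrchardConfig()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=8)
    x0, y0, x1, y1 = field_extent(config)
    terrain = generate_terrain(
        (x1 - x0, y1 - y0), pixel_size, slope=terrain_slope,
        roughness_sd=terrain_roughness_sd, seed=int(seeds[0]),
        origin_xy=(x0, y0), config=config)
    crowns, truth1 = generate_orchard(
        config, crown_params=crown_params, jitter_sd=jitter_sd,
        seed=int(seeds[1]), terrain=terrain, date_label=dates[0])

    specs = {
        "traditional": PruningSpec("traditional", volume_removal_fraction=0.36,
                                   seed=int(seeds[2])),
        "adapted": PruningSpec("adapted", volume_removal_fraction=0.42,
                               seed=int(seeds[3])),
        "mechanical": PruningSpec("mechanical", seed=int(seeds[4])),
    }
    if pruning_specs:
        specs.update(pruning_specs)

    pruned: list[CrownModel] = []
    for treatment in sorted({c.treatment for c in crowns}):
        block = [c for c in crowns if c.treatment == treatment]
        block_pruned, _ = apply_pruning(block, specs[treatment], date_label=dates[1])
        pruned.extend(block_pruned)
    pruned.sort(key=lambda c: c.tree_id)
    truth2 = truth_from_crowns(pruned, dates[1])

    grown = apply_regrowth(pruned, growth_fraction_by_severity,
                           seed=int(seeds[5]), noise_cv=growth_noise_cv)
    truth3 = truth_from_crowns(grown, dates[2])

    out: dict[str, tuple[MultiLayerScene, OrchardTruth]] = {}
    for label, date_crowns, truth, noise_seed in (
            (dates[0], crowns, truth1, int(seeds[6]) % (2 ** 31 - 1)),
            (dates[1], pruned, truth2, int(seeds[7]) % (2 ** 31 - 1)),
            (dates[2], grown, truth3, (int(seeds[6]) + 1) % (2 ** 31 - 1))):
        dsm = render_dsm(terrain, date_crowns, noise_sd=noise_sd, seed=noise_seed)
        out[label] = (MultiLayerScene(dsm=dsm, date_label=label), truth)
    return out
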