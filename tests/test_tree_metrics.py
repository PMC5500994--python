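"""Per-tree feature extraction: ground reference, height, area, volume, grid id."""

import math

import numpy as np
import pytest

from orchard3d.obia_delineation import TreeMask, delineate
from orchard3d.raster_model import GridTransform, OrchardConfig
from orchard3d.synthetic_orchard import (
    CrownModel,
    generate_orchard,
    generate_terrain,
    render_dsm,
)
from orchard3d.tree_metrics import (
    LandlockedTreeError,
    TreeObject,
    assign_grid_position,
    compute_area,
    compute_ground_reference,
    compute_height,
    compute_volume,
    extract_features,
)

from conftest import make_grid


def _mask_from_labels(labels, pixel_size=0.5):
    labels = np.asarray(labels, dtype=np.int32)
    return TreeMask(labels=labels, n_trees=int(labels.max()),
                    transform=GridTransform(0.0, labels.shape[0] * pixel_size,
                                            pixel_size))


def _tree_from_mask(mask, tree_id=1):
    rr, cc = np.nonzero(mask.labels == tree_id)
    return TreeObject(tree_id=tree_id, rows=rr, cols=cc,
                      bbox=(rr.min(), rr.max() + 1, cc.min(), cc.max() + 1))


class TestGroundReference:
    def test_flat_soil_gives_soil_elevation(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[8:12, 8:12] = 1
        mask = _mask_from_labels(labels)
        dsm = make_grid(np.full((20, 20), 100.0), pixel_size=0.5)
        tree = _tree_from_mask(mask)
        assert compute_ground_reference(tree, mask, dsm) == pytest.approx(100.0)

    def test_mean_of_mixed_buffer(self):
        # soil split into two halves at different elevations -> mean of the ring
        vals = np.full((21, 21), 100.0)
        vals[:, 11:] = 101.0
        labels = np.zeros((21, 21), dtype=int)
        labels[9:13, 9:13] = 1
        vals[labels == 1] = 105.0
        mask = _mask_from_labels(labels, pixel_size=0.5)
        dsm = make_grid(vals, pixel_size=0.5)
        tree = _tree_from_mask(mask)
        ref = compute_ground_reference(tree, mask, dsm, buffer_m=1.0)
        # ring spans the boundary asymmetrically; mean lies strictly between
        assert 100.0 < ref < 101.0

    def test_other_trees_excluded_from_buffer(self):
        vals = np.full((20, 20), 100.0)
        labels = np.zeros((20, 20), dtype=int)
        labels[8:12, 8:12] = 1
        labels[8:12, 13:16] = 2  # a neighbour inside the buffer
        vals[labels == 2] = 104.0
        mask = _mask_from_labels(labels)
        dsm = make_grid(vals, pixel_size=0.5)
        tree = _tree_from_mask(mask, 1)
        assert compute_ground_reference(tree, mask, dsm) == pytest.approx(100.0)

    def test_landlocked_tree_raises(self):
        labels = np.ones((20, 20), dtype=int)
        labels[5:15, 5:15] = 2  # tree 2 fully enclosed by tree 1
        mask = _mask_from_labels(labels)
        dsm = make_grid(np.full((20, 20), 102.0), pixel_size=0.5)
        tree = _tree_from_mask(mask, 2)
        with pytest.raises(LandlockedTreeError):
            compute_ground_reference(tree, mask, dsm)

    def test_buffer_widens_until_soil_found(self):
        # nearest soil is ~2 m away: the 1 m ring is empty but widening succeeds
        labels = np.zeros((40, 40), dtype=int)
        labels[16:24, 16:24] = 1
        labels[np.array([14, 15, 24, 25])[:, None], 12:28] = 3
        labels[12:28, np.array([14, 15, 24, 25])] = 3
        mask = _mask_from_labels(labels)
        dsm = make_grid(np.full((40, 40), 100.0), pixel_size=0.5)
        tree = _tree_from_mask(mask, 1)
        assert compute_ground_reference(tree, mask, dsm) == pytest.approx(100.0)


class TestHeightAreaVolume:
    def test_height_is_max_minus_ground(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[4:7, 4:7] = 1
        mask = _mask_from_labels(labels)
        vals = np.full((10, 10), 100.0)
        vals[5, 5] = 104.10
        dsm = make_grid(vals, pixel_size=0.5)
        tree = _tree_from_mask(mask)
        assert compute_height(tree, dsm, 100.0) == pytest.approx(4.10)

    def test_height_quantile_softens_spikes(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[2:8, 2:8] = 1
        mask = _mask_from_labels(labels)
        vals = np.full((10, 10), 103.0)
        vals[5, 5] = 110.0  # an outlier spike
        dsm = make_grid(vals, pixel_size=0.5)
        tree = _tree_from_mask(mask)
        assert compute_height(tree, dsm, 100.0) == pytest.approx(10.0)
        assert compute_height(tree, dsm, 100.0,
                              height_quantile=0.95) == pytest.approx(3.0, abs=0.5)

    def test_area_counts_pixels(self):
        tree = TreeObject(tree_id=1, rows=np.zeros(6152, dtype=int),
                          cols=np.arange(6152), bbox=(0, 1, 0, 6152))
        assert compute_area(tree, 0.05) == pytest.approx(15.38)
        one_px = TreeObject(tree_id=2, rows=np.array([0]), cols=np.array([0]),
                            bbox=(0, 1, 0, 1))
        assert compute_area(one_px, 0.05) == pytest.approx(0.0025)

    def test_volume_sums_clamped_pixel_columns(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[1, 1] = 1
        labels[1, 2] = 1
        mask = _mask_from_labels(labels, pixel_size=0.2)
        vals = np.full((4, 4), 100.0)
        vals[1, 1] = 102.0   # 2 m above ground ref
        vals[1, 2] = 99.0    # below ground ref: clamps to 0
        dsm = make_grid(vals, pixel_size=0.2)
        tree = _tree_from_mask(mask)
        assert compute_volume(tree, dsm, 100.0, 0.2) == pytest.approx(0.08)

    def test_volume_bounded_by_area_times_height(self):
        terrain = generate_terrain((20.0, 20.0), 0.05, base_elev=100.0)
        c = CrownModel(center_xy=(10.0, 10.0), trunk_base_elev=100.0,
                       crown_base_height=0.6, apex_height=4.0,
                       semi_axis_x=1.8, semi_axis_y=2.1)
        dsm = render_dsm(terrain, [c])
        mask = delineate(dsm)
        rec = extract_features(mask, dsm)[0]
        assert rec.volume_m3 <= rec.area_m2 * rec.height_m + 1e-9


class TestGridPosition:
    def _tree_at(self, x, y, tree_id=1):
        t = TreeObject(tree_id=tree_id, rows=np.array([0]), cols=np.array([0]),
                       bbox=(0, 1, 0, 1))
        t.centroid_xy = (x, y)
        return t

    def test_centroid_at_node(self, mini_config):
        x, y = mini_config.node_xy(3, 2)
        (tree,) = assign_grid_position([self._tree_at(float(x), float(y))],
                                       mini_config)
        assert (tree.row, tree.column) == (3, 2)
        assert tree.treatment == "mechanical"
        assert tree.reliable

    def test_offset_centroid_rounds_to_nearest_node(self, mini_config):
        x, y = mini_config.node_xy(3, 2)
        (tree,) = assign_grid_position(
            [self._tree_at(float(x) + 0.35, float(y) - 0.35)], mini_config)
        assert (tree.row, tree.column) == (3, 2)
        assert tree.reliable

    def test_far_centroid_flagged_off_grid(self, mini_config):
        x, y = mini_config.node_xy(1, 1)
        (tree,) = assign_grid_position(
            [self._tree_at(float(x) - 5.0, float(y) - 5.0)], mini_config)
        assert not tree.reliable
        assert "off-grid" in tree.flags

    def test_duplicate_node_keeps_nearer_centroid(self, mini_config):
        x, y = mini_config.node_xy(2, 2)
        near = self._tree_at(float(x) + 0.1, float(y), tree_id=1)
        far = self._tree_at(float(x) + 1.2, float(y), tree_id=2)
        assign_grid_position([far, near], mini_config)
        assert near.reliable
        assert not far.reliable and "duplicate-node" in far.flags


class TestExtractFeatures:
    def test_single_crown_parameter_recovery(self, single_crown_scene):
        dsm, crown = single_crown_scene
        mask = delineate(dsm)
        records = extract_features(mask, dsm)
        assert len(records) == 1
        rec = records[0]
        assert rec.height_m == pytest.approx(3.0, abs=0.05)
        assert rec.area_m2 == pytest.approx(crown.projected_area(), rel=0.05)
        assert rec.volume_m3 == pytest.approx(crown.volume(), rel=0.05)
        assert rec.geometry is not None
        assert rec.geometry.area == pytest.approx(rec.area_m2, rel=0.05)

    def test_empty_mask_yields_no_records(self, flat_dsm):
        mask = delineate(flat_dsm)
        assert extract_features(mask, flat_dsm) == []

    def test_mini_orchard_recovery_and_sorting(self, mini_config):
        terrain = generate_terrain((50.0, 40.0), 0.05, origin_xy=(0.0, 0.0),
                                   base_elev=100.0, config=mini_config)
        crowns, truth = generate_orchard(mini_config, seed=4, terrain=terrain)
        dsm = render_dsm(terrain, crowns)
        mask = delineate(dsm)
        records = extract_features(mask, dsm, mini_config)
        assert len(records) == 12
        assert all(r.reliable for r in records)
        keys = [(r.row, r.column) for r in records]
        assert keys == sorted(keys)
        by_pos = truth.by_position()
        for rec in records:
            t = by_pos[(rec.row, rec.column)]
            assert rec.height_m == pytest.approx(t.true_height_m, abs=0.05)
            assert rec.area_m2 == pytest.approx(t.true_area_m2, rel=0.05)
            assert rec.volume_m3 == pytest.approx(t.true_volume_m3, rel=0.05)
            assert rec.treatment == t.treatment

    def test_translation_equivariance(self, mini_config):
        """Shifting the raster origin by whole pixels shifts centroids only."""
        terrain = generate_terrain((50.0, 40.0), 0.05, origin_xy=(0.0, 0.0),
                                   base_elev=100.0, config=mini_config)
        crowns, _ = generate_orchard(mini_config, seed=4, terrain=terrain)
        dsm = render_dsm(terrain, crowns)
        mask = delineate(dsm)
        recs = extract_features(mask, dsm, mini_config, with_geometry=False)

        shift = 40 * dsm.pixel_size  # 40 pixels
        shifted = make_grid(dsm.elevations,
                            pixel_size=dsm.pixel_size,
                            x_min=dsm.transform.x_min + shift,
                            y_max=dsm.transform.y_max + shift)
        cfg2 = OrchardConfig(
            origin_xy=(mini_config.origin_xy[0] + shift,
                       mini_config.origin_xy[1] + shift),
            n_rows=mini_config.n_rows, n_cols=mini_config.n_cols,
            treatment_blocks=mini_config.treatment_blocks)
        mask2 = delineate(shifted)
        recs2 = extract_features(mask2, shifted, cfg2, with_geometry=False)
        assert len(recs) == len(recs2)
        for a, b in zip(recs, recs2):
            assert b.x - a.x == pytest.approx(shift, abs=1e-9)
            assert b.y - a.y == pytest.approx(shift, abs=1e-9)
            assert b.area_m2 == pytest.approx(a.area_m2, abs=1e-12)
            assert b.height_m == pytest.approx(a.height_m, abs=1e-12)
            assert b.volume_m3 == pytest.approx(a.volume_m3, abs=1e-12)

    def test_noise_bias_on_heights_is_bounded(self, mini_config):
        """Gaussian DSM noise of sd sigma moves mean height by < 3 sigma."""
        terrain = generate_terrain((50.0, 40.0), 0.05, origin_xy=(0.0, 0.0),
                                   base_elev=100.0, config=mini_config)
        crowns, truth = generate_orchard(mini_config, seed=4, terrain=terrain)
        sigma = 0.02
        noisy = render_dsm(terrain, crowns, noise_sd=sigma, seed=21)
        mask = delineate(noisy)
        records = extract_features(mask, noisy, mini_config)
        by_pos = truth.by_position()
        diffs = [r.height_m - by_pos[(r.row, r.column)].true_height_m
                 for r in records]
        assert abs(float(np.mean(diffs))) < 3 * sigma

    def test_nodata_fraction_flags_unreliable(self):
        labels = np.zeros((30, 30), dtype=int)
        labels[10:20, 10:20] = 1
        mask = _mask_from_labels(labels, pixel_size=0.5)
        vals = np.full((30, 30), 100.0)
        vals[10:20, 10:20] = 103.0
        nodata = np.zeros((30, 30), dtype=bool)
        nodata[12:18, 12:18] = True  # 36% of the crown footprint
        labels[nodata] = 0
        dsm = make_grid(vals, pixel_size=0.5, nodata_mask=nodata)
        records = extract_features(mask, dsm)
        assert len(records) == 1
        assert not records[0].reliable
        assert "excess-nodata" in records[0].flags
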