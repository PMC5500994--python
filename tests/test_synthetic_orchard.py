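"""Synthetic orchard generator: terrain, crowns, rendering, pruning, regrowth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orchard3d.raster_model import OrchardConfig
from orchard3d.synthetic_orchard import (
    CrownModel,
    CrownParams,
    PruningSpec,
    apply_pruning,
    apply_regrowth,
    field_extent,
    generate_orchard,
    generate_terrain,
    render_dsm,
    truth_from_crowns,
)


def crown(a=2.0, b=2.0, apex=3.0, base=0.0, **kw):
    return CrownModel(center_xy=(0.0, 0.0), trunk_base_elev=0.0,
                      crown_base_height=base, apex_height=apex,
                      semi_axis_x=a, semi_axis_y=b, **kw)


class TestTerrain:
    def test_flat_when_no_slope_no_roughness(self):
        t = generate_terrain((10.0, 10.0), 0.5, base_elev=100.0)
        assert np.all(t.elevations == 100.0)

    def test_deterministic_for_fixed_seed(self):
        a = generate_terrain((30.0, 30.0), 0.25, roughness_sd=0.1, seed=42)
        b = generate_terrain((30.0, 30.0), 0.25, roughness_sd=0.1, seed=42)
        np.testing.assert_array_equal(a.elevations, b.elevations)

    def test_slope_gives_analytic_elevation_difference(self):
        t = generate_terrain((100.0, 10.0), 0.5, slope=(0.01, 0.0))
        # 1 cm/m over 100 m: edge-to-edge difference approaches 1.0 m
        diff = t.elevations[:, -1].mean() - t.elevations[:, 0].mean()
        assert diff == pytest.approx(1.0 - 0.01 * 0.5, abs=1e-9)

    def test_extent_must_cover_plantation(self, mini_config):
        with pytest.raises(ValueError, match="footprint"):
            generate_terrain((5.0, 5.0), 0.5, origin_xy=(10.0, 10.0),
                             config=mini_config)


class TestCrownGeometry:
    def test_half_ellipsoid_closed_form(self):
        c = crown(a=2.0, b=2.0, apex=3.0)
        assert c.volume() == pytest.approx(2.0 / 3.0 * math.pi * 2 * 2 * 3)
        assert c.projected_area() == pytest.approx(math.pi * 4.0)
        assert c.visible_height == 3.0

    def test_closed_form_matches_numeric_integration(self):
        c = crown(a=1.8, b=2.2, apex=4.1, base=0.6)
        assert c._volume_numeric(0.01) == pytest.approx(c.volume(), rel=0.01)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(a=st.floats(1.0, 2.4), b=st.floats(1.0, 2.4),
           apex=st.floats(2.5, 4.5), base=st.floats(0.0, 0.8),
           top=st.none() | st.floats(1.5, 4.2), skirt=st.none() | st.floats(0.0, 1.0))
    def test_truncated_volumes_match_brute_force(self, a, b, apex, base, top, skirt):
        """The top-cut/skirt frustum integral agrees with 1 cm integration."""
        if apex - base < 0.5:
            apex = base + 0.5
        if top is not None and top <= (skirt or 0.0) + 0.2:
            top = (skirt or 0.0) + 0.5
        c = crown(a=a, b=b, apex=apex, base=base, top_cut_height=top,
                  skirt_height=skirt)
        assert c._volume_numeric(0.01) == pytest.approx(c.volume(),
                                                        rel=0.01, abs=0.02)

    def test_degenerate_crown_rejected(self):
        with pytest.raises(ValueError):
            crown(apex=0.5, base=0.6)
        with pytest.raises(ValueError):
            crown(a=-1.0)


class TestGenerateOrchard:
    def test_full_study_layout_produces_648_trees(self):
        crowns, truth = generate_orchard(OrchardConfig(), seed=3)
        assert len(crowns) == 648
        rows = {c.row for c in crowns}
        cols = {c.column for c in crowns}
        assert rows == set(range(1, 28))
        assert cols == set(range(1, 25))
        assert all(t.true_volume_m3 > 0 for t in truth.trees)

    def test_zero_jitter_centers_on_grid_nodes(self, mini_config):
        crowns, _ = generate_orchard(mini_config, jitter_sd=0.0, seed=0)
        for c in crowns:
            x, y = mini_config.node_xy(c.row, c.column)
            assert c.center_xy == (float(x), float(y))

    def test_overlapping_crowns_rejected_unless_allowed(self, mini_config):
        params = CrownParams(semi_along_range=(2.2, 2.4))  # > half of 4 m spacing
        with pytest.raises(ValueError, match="overlap"):
            generate_orchard(mini_config, crown_params=params, jitter_sd=0.0, seed=0)
        crowns, _ = generate_orchard(mini_config, crown_params=params,
                                     jitter_sd=0.0, seed=0, allow_overlap=True)
        assert len(crowns) == mini_config.n_trees

    def test_truth_mirrors_crown_analytics(self, mini_config):
        crowns, truth = generate_orchard(mini_config, seed=1)
        for c, t in zip(crowns, truth.trees):
            assert t.true_area_m2 == pytest.approx(c.projected_area())
            assert t.true_volume_m3 == pytest.approx(c.volume())
            assert t.true_height_m == pytest.approx(c.apex_height)


class TestRenderDsm:
    def test_no_crowns_no_noise_is_terrain(self, flat_dsm):
        out = render_dsm(flat_dsm, [])
        np.testing.assert_array_equal(out.elevations, flat_dsm.elevations)

    def test_apex_recovered_within_half_pixel(self, flat_dsm):
        c = CrownModel(center_xy=(10.0, 10.0), trunk_base_elev=100.0,
                       crown_base_height=0.0, apex_height=4.0,
                       semi_axis_x=2.0, semi_axis_y=2.0)
        out = render_dsm(flat_dsm, [c])
        top = out.elevations.max() - 100.0
        assert top == pytest.approx(4.0, abs=flat_dsm.pixel_size / 2)

    def test_noise_is_reproducible(self, flat_dsm):
        a = render_dsm(flat_dsm, [], noise_sd=0.02, seed=9)
        b = render_dsm(flat_dsm, [], noise_sd=0.02, seed=9)
        np.testing.assert_array_equal(a.elevations, b.elevations)
        assert a.elevations.std() == pytest.approx(0.02, rel=0.1)


class TestPruning:
    def test_mechanical_top_cut_sets_truth_height(self):
        c = crown(apex=4.2, base=0.6, top_cut_height=None)
        pruned, truth = apply_pruning([c], PruningSpec("mechanical",
                                                       top_cut_height_m=3.75))
        assert truth.trees[0].true_height_m == 3.75
        assert pruned[0].volume() < c.volume()

    def test_mechanical_spares_short_trees(self):
        c = crown(apex=3.2, base=0.6)
        pruned, truth = apply_pruning([c], PruningSpec("mechanical",
                                                       top_cut_height_m=3.75))
        assert truth.trees[0].true_height_m == pytest.approx(3.2)
        # the 0.7 m low cut trims only the skirt: area nearly unchanged
        assert truth.trees[0].true_area_m2 == pytest.approx(c.projected_area(),
                                                            rel=5e-3)

    def test_traditional_removes_exact_volume_fraction(self):
        c = crown(a=2.0, b=2.0, apex=3.0)
        v0 = c.volume()
        assert v0 == pytest.approx(25.133, abs=5e-4)
        pruned, truth = apply_pruning(
            [c], PruningSpec("traditional", volume_removal_fraction=0.36))
        assert truth.trees[0].true_volume_m3 == pytest.approx(25.133 * 0.64,
                                                              abs=1e-3)
        assert truth.trees[0].true_volume_m3 == pytest.approx(16.085, abs=1e-3)
        assert pruned[0].pruning_severity == pytest.approx(0.36)

    def test_zero_fraction_is_identity(self):
        c = crown()
        pruned, truth = apply_pruning([c], PruningSpec("traditional"))
        assert pruned[0].semi_axis_x == c.semi_axis_x
        assert truth.trees[0].true_volume_m3 == pytest.approx(c.volume())

    def test_pruned_volume_never_exceeds_unpruned(self):
        rng = np.random.default_rng(5)
        for treatment, kw in (("traditional", dict(volume_removal_fraction=0.4)),
                              ("adapted", dict(volume_removal_fraction=0.42)),
                              ("mechanical", {})):
            crowns = [crown(a=rng.uniform(1.2, 2), b=rng.uniform(1.2, 2),
                            apex=rng.uniform(3.3, 4.5), base=0.6)
                      for _ in range(10)]
            pruned, _ = apply_pruning(crowns, PruningSpec(treatment, seed=1, **kw))
            for before, after in zip(crowns, pruned):
                assert after.volume() <= before.volume() + 1e-9

    def test_extreme_fraction_rejected(self):
        c = crown(a=0.06, b=0.06)
        with pytest.raises(ValueError, match="semi-axes"):
            apply_pruning([c], PruningSpec("traditional",
                                           volume_removal_fraction=0.9))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PruningSpec("topiary")
        with pytest.raises(ValueError):
            PruningSpec("traditional", volume_removal_fraction=1.0)
        with pytest.raises(ValueError):
            PruningSpec("mechanical", top_cut_height_m=0.5)


class TestRegrowth:
    def test_zero_growth_is_identity(self):
        c = crown(pruning_severity=0.36)
        grown = apply_regrowth([c], {k: 0.0 for k in
                                     ("<10%", "10-30%", "30-50%", ">50%")})
        assert grown[0].semi_axis_x == c.semi_axis_x

    def test_growth_fraction_multiplies_volume(self):
        c = crown(a=2.0 * math.sqrt(0.64), b=2.0 * math.sqrt(0.64),
                  apex=3.0, pruning_severity=0.36)
        assert c.volume() == pytest.approx(16.085, abs=1e-3)
        grown = apply_regrowth([c], {"30-50%": 0.60})
        assert grown[0].volume() == pytest.approx(16.085 * 1.60, abs=2e-3)
        assert grown[0].volume() == pytest.approx(25.736, abs=2e-3)
        assert grown[0].apex_height == c.apex_height  # horizontal regrowth only

    def test_reproducible_with_noise(self):
        crowns = [crown(pruning_severity=0.2) for _ in range(5)]
        a = apply_regrowth(crowns, seed=7, noise_cv=0.3)
        b = apply_regrowth(crowns, seed=7, noise_cv=0.3)
        assert [c.semi_axis_x for c in a] == [c.semi_axis_x for c in b]

    def test_negative_growth_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            apply_regrowth([crown()], {"<10%": -0.1})


def test_field_extent_covers_all_nodes(mini_config):
    x0, y0, x1, y1 = field_extent(mini_config, margin_m=6.0)
    for row in (1, mini_config.n_rows):
        for col in (1, mini_config.n_cols):
            x, y = mini_config.node_xy(row, col)
            assert x0 <= x <= x1 and y0 <= y <= y1
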