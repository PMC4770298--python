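"""Segmentation, volume integration, half-depth area, profiles."""

import math

import numpy as np
import pytest

from uscape import (
    DepthMap,
    FeatureSpec,
    cross_section,
    generate_well_array,
    half_depth_area,
    integrate_volume,
    longitudinal_profile,
    measure_regions,
    render_depth_field,
    segment_features,
)
from uscape.morphometry import MeasurementError
from uscape.synthetic import basin_well_volume_um3


def as_map(field_or_array, pitch=None):
    if hasattr(field_or_array, "depth"):
        return DepthMap(field_or_array.depth, field_or_array.pitch_um)
    return DepthMap(np.asarray(field_or_array, dtype=float), pitch)


class TestSegmentFeatures:
    def test_well_grid_count_conserved(self):
        spec = FeatureSpec("basin_well", (0, 0), radius=35, depth=9)
        fld, _ = generate_well_array([100], [spec], seed=0, pitch_um=4.0)
        regions = segment_features(as_map(fld), min_depth_um=1.0)
        assert len(regions) == 100

    def test_touching_wells_merge_into_one_region(self):
        depth = np.zeros((20, 40))
        depth[5:15, 5:20] = 10.0
        depth[5:15, 20:35] = 10.0  # adjacent blocks share an edge
        regions = segment_features(as_map(depth, 2.0), min_depth_um=1.0)
        assert len(regions) == 1

    def test_otsu_default_threshold_splits_bimodal_map(self):
        depth = np.zeros((30, 30))
        depth[10:20, 10:20] = 12.0
        regions = segment_features(as_map(depth, 2.0))
        assert len(regions) == 1
        assert regions[0].n_pixels == 100

    def test_min_area_filters_specks(self):
        depth = np.zeros((20, 20))
        depth[2, 2] = 10.0  # single-pixel speck
        depth[10:16, 10:16] = 10.0
        regions = segment_features(as_map(depth, 2.0), min_depth_um=1.0,
                                   min_area_um2=5 * 4.0)
        assert len(regions) == 1

    def test_empty_map_gives_empty_list(self):
        assert segment_features(as_map(np.zeros((10, 10)), 2.0)) == []

    def test_label_order_row_major_by_centroid(self):
        depth = np.zeros((40, 40))
        depth[2:8, 30:36] = 5.0   # top right
        depth[2:8, 2:8] = 5.0     # top left
        depth[30:36, 2:8] = 5.0   # bottom left
        regions = segment_features(as_map(depth, 2.0), min_depth_um=1.0)
        centroids = [r.centroid_um for r in regions]
        assert centroids == sorted(centroids, key=lambda c: (c[1], c[0]))
        assert [r.label for r in regions] == [1, 2, 3]


class TestIntegrateVolume:
    def test_uniform_block_arithmetic(self):
        # 10^4 px of 100 um depth at 10 um pitch -> 100 nL
        depth = np.zeros((120, 120))
        depth[10:110, 10:110] = 100.0
        dmap = as_map(depth, 10.0)
        region = segment_features(dmap, min_depth_um=1.0)[0]
        assert integrate_volume(dmap, region) == pytest.approx(100.0)

    def test_rendered_basin_well_matches_closed_form(self, basin_field):
        dmap = as_map(basin_field)
        region = segment_features(dmap, min_depth_um=0.05)[0]
        expected = basin_well_volume_um3(40, 10.9) * 1e-6
        assert integrate_volume(dmap, region) == pytest.approx(expected,
                                                               rel=0.02)

    def test_sagging_volume_deficit_grows_with_radius(self):
        # deficit fraction = k r^3 / (pi r^2 d): cubic loss vs quadratic design
        k, d = 0.05, 200.0
        fracs = []
        for r in (1250.0, 3000.0, 6500.0):
            feat = FeatureSpec("sagging_chamber", (r * 1.2, r * 1.2), r, d,
                               params={"k_sag": k})
            fld = render_depth_field([feat], (2.4 * r, 2.4 * r), r / 100.0)
            dmap = as_map(fld)
            region = segment_features(dmap, min_depth_um=0.5)[0]
            measured = integrate_volume(dmap, region)
            designed = math.pi * r**2 * d * 1e-6
            fracs.append(1.0 - measured / designed)
        assert fracs[0] < fracs[1] < fracs[2]
        for r, frac in zip((1250.0, 3000.0, 6500.0), fracs):
            assert frac == pytest.approx(k * r / (math.pi * d), rel=0.05)

    def test_volume_additivity_over_disjoint_regions(self):
        depth = np.zeros((30, 60))
        depth[5:15, 5:15] = 10.0
        depth[5:15, 40:55] = 7.0
        dmap = as_map(depth, 2.0)
        regions = segment_features(dmap, min_depth_um=1.0)
        total = sum(integrate_volume(dmap, r) for r in regions)
        assert total == pytest.approx(depth.sum() * 4.0 * 1e-6, rel=1e-12)

    def test_volume_invariant_to_90_degree_rotation(self, basin_field):
        dmap = as_map(basin_field)
        v1 = integrate_volume(dmap, segment_features(dmap, 0.05)[0])
        rot = DepthMap(np.rot90(basin_field.depth).copy(),
                       basin_field.pitch_um)
        v2 = integrate_volume(rot, segment_features(rot, 0.05)[0])
        assert v1 == v2

    def test_volume_converges_under_pitch_refinement(self):
        feat = FeatureSpec("basin_well", (60, 60), radius=40, depth=10.9)
        coarse = render_depth_field([feat], (120, 120), 2.0)
        fine = render_depth_field([feat], (120, 120), 1.0)
        assert abs(fine.volume_nl() / coarse.volume_nl() - 1.0) <= 0.01

    def test_segmentation_recovers_99_percent_of_array_volume(self):
        spec = FeatureSpec("basin_well", (0, 0), radius=35, depth=9)
        fld, truth = generate_well_array([64], [spec],
                                         jitter_sd={"depth": 0.4}, seed=3,
                                         pitch_um=2.0)
        dmap = as_map(fld)
        regions = segment_features(dmap, min_depth_um=0.05)
        recovered = sum(integrate_volume(dmap, r) for r in regions)
        assert recovered >= 0.99 * truth.volumes_nl.sum()

    def test_region_with_no_valid_pixels_rejected(self):
        depth = np.zeros((10, 10))
        depth[2:7, 2:7] = 5.0
        dmap = as_map(depth, 2.0)
        region = segment_features(dmap, 1.0)[0]
        dmap_masked = DepthMap(depth, 2.0, mask=np.zeros_like(depth, bool))
        with pytest.raises(MeasurementError):
            integrate_volume(dmap_masked, region)


class TestHalfDepthArea:
    def test_flat_bottom_equals_full_area(self):
        depth = np.zeros((30, 30))
        depth[5:25, 5:25] = 10.0
        dmap = as_map(depth, 2.0)
        region = segment_features(dmap, 1.0)[0]
        assert half_depth_area(dmap, region) == pytest.approx(region.area_um2)

    @pytest.mark.parametrize("d", [8.0, 16.0])
    def test_cone_half_depth_area_quarter_of_mouth(self, d):
        # similar triangles: radius at half depth is half the mouth radius,
        # so area is a quarter of the mouth area — independent of cone depth
        feat = FeatureSpec("cone_well", (80, 80), radius=50, depth=d)
        fld = render_depth_field([feat], (160, 160), 1.0)
        dmap = as_map(fld)
        region = segment_features(dmap, min_depth_um=d * 0.01)[0]
        mouth = math.pi * 50**2
        # exact similar-triangles check against the raw apex; the default
        # median-smoothed reference biases a pointed apex a few % larger
        assert half_depth_area(dmap, region, smooth=False) == pytest.approx(
            mouth / 4.0, rel=0.05)
        assert half_depth_area(dmap, region) == pytest.approx(mouth / 4.0,
                                                              rel=0.10)

    def test_all_zero_region_rejected(self):
        depth = np.zeros((10, 10))
        depth[2:6, 2:6] = 4.0
        dmap = as_map(depth, 2.0)
        region = segment_features(dmap, 1.0)[0]
        zero_map = as_map(np.zeros((10, 10)), 2.0)
        with pytest.raises(MeasurementError):
            half_depth_area(zero_map, region)


class TestCrossSection:
    def test_flat_region_constant_profile(self):
        dmap = as_map(np.full((40, 40), 25.0), 2.0)
        cs = cross_section(dmap, (4, 40), (76, 40))
        assert np.allclose(cs.depths_um, 25.0)
        assert np.all(np.diff(cs.positions_um) > 0)

    def test_gaussian_channel_width_recovered_by_fit(self):
        from scipy.optimize import curve_fit

        feat = FeatureSpec("ablated_channel", (200, 100), radius=180,
                           depth=30, params={"width_um": 25.0})
        fld = render_depth_field([feat], (400, 200), 2.0)
        cs = cross_section(as_map(fld), (200, 10), (200, 190))

        def gauss(x, a, mu, sig):
            return a * np.exp(-0.5 * ((x - mu) / sig) ** 2)

        popt, _ = curve_fit(gauss, cs.positions_um, cs.depths_um,
                            p0=[20, 90, 15])
        assert popt[2] == pytest.approx(25.0, rel=0.05)
        assert popt[0] == pytest.approx(30.0, rel=0.05)

    def test_cylinder_center_cut_is_top_hat_of_width_2r(self, cylinder_field):
        dmap = as_map(cylinder_field)
        cs = cross_section(dmap, (30, 600), (1170, 600))
        widths = cs.positions_um[cs.depths_um > 50.0]
        measured = widths.max() - widths.min()
        assert measured == pytest.approx(1000.0, abs=2 * dmap.pitch_um)

    def test_zero_length_line_rejected(self):
        dmap = as_map(np.zeros((10, 10)), 2.0)
        with pytest.raises(ValueError, match="zero length"):
            cross_section(dmap, (5, 5), (5, 5))

    def test_endpoint_outside_map_rejected(self):
        dmap = as_map(np.zeros((10, 10)), 2.0)
        with pytest.raises(IndexError):
            cross_section(dmap, (5, 5), (100, 5))


class TestLongitudinalProfile:
    def _channel_map(self, wall_jitter_sd=0.0, seed=0):
        """Straight channel along x with optionally jittered wall positions."""
        rng = np.random.default_rng(seed)
        depth = np.zeros((60, 200))
        for col in range(200):
            jit = rng.normal(0, wall_jitter_sd) if wall_jitter_sd else 0.0
            half_w = 15 + jit
            lo, hi = int(round(30 - half_w)), int(round(30 + half_w))
            depth[lo:hi, col] = 20.0
        return as_map(depth, 2.0)

    def test_16_slices_over_uniform_channel_zero_envelope(self):
        dmap = self._channel_map()
        cuts, mean, sd = longitudinal_profile(dmap, (10, 60), (390, 60),
                                              n_slices=16, width_um=100)
        assert len(cuts) == 16
        assert np.allclose(sd, 0.0)
        assert mean.max() == pytest.approx(20.0)

    def test_wall_jitter_concentrates_sd_at_walls(self):
        dmap = self._channel_map(wall_jitter_sd=1.5, seed=4)
        _, mean, sd = longitudinal_profile(dmap, (10, 60), (390, 60),
                                           n_slices=16, width_um=100)
        n = sd.size
        floor = sd[n // 2 - 3: n // 2 + 3]
        walls = sd[(mean > 2.0) & (mean < 18.0)]
        assert walls.size > 0
        assert walls.mean() > 5 * max(floor.mean(), 1e-9)

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError, match="slices"):
            longitudinal_profile(self._channel_map(), (10, 60), (390, 60),
                                 n_slices=1)


class TestMeasureRegions:
    def test_table_columns_and_values(self, basin_field):
        dmap = as_map(basin_field)
        regions = segment_features(dmap, 0.05)
        df = measure_regions(dmap, regions)
        assert list(df.columns) == [
            "label", "centroid_x_um", "centroid_y_um", "area_um2",
            "max_depth_um", "volume_nL", "half_depth_area_um2",
        ]
        assert len(df) == 1
        assert df.loc[0, "max_depth_um"] == pytest.approx(10.9, rel=1e-6)
        assert df.loc[0, "centroid_x_um"] == pytest.approx(60.0, abs=1.0)
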