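"""Resistance layers: TRI, natural breaks, the class mappings, and the
cumulative 1-10 surface."""

import numpy as np
import pytest
from shapely.geometry import Point, box

import waveways as w
from waveways import resistance as rs
from waveways.grid import Grid


class TestTRI:
    def test_constant_elevation_is_flat(self):
        tri = rs.terrain_ruggedness_index(Grid(np.full((5, 5), 42.0)))
        assert np.all(tri.data == 0)

    def test_single_peak_hand_value(self):
        z = np.zeros((3, 3))
        z[1, 1] = 10.0
        tri = rs.terrain_ruggedness_index(Grid(z))
        assert tri.data[1, 1] == pytest.approx(np.sqrt(8 * 100))

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        z = rng.uniform(0, 300, (8, 8))
        a = rs.terrain_ruggedness_index(Grid(z)).data
        b = rs.terrain_ruggedness_index(Grid(z + 1234.5)).data
        assert np.allclose(a, b)

    def test_edge_cells_use_available_neighbors(self):
        z = np.zeros((3, 3))
        z[0, 0] = 5.0
        tri = rs.terrain_ruggedness_index(Grid(z))
        # corner has 3 neighbours, each differing by 5
        assert tri.data[0, 0] == pytest.approx(np.sqrt(3 * 25))

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            rs.terrain_ruggedness_index(Grid(np.zeros((2, 5))))


class TestJenks:
    def test_two_obvious_clusters(self):
        breaks = rs.jenks_breaks([1, 2, 3, 100, 101, 102], 2)
        assert breaks[0] == 1 and breaks[-1] == 102
        assert 3 <= breaks[1] < 100

    def test_k_equals_distinct_values(self):
        vals = [1.0, 5.0, 9.0, 14.0]
        breaks = rs.jenks_breaks(vals, 4)
        assert len(breaks) == 5

    def test_optimality_against_random_breaksets(self):
        """The DP solution's within-class SSD beats 1000 random partitions."""
        rng = np.random.default_rng(42)
        vals = np.sort(rng.uniform(0, 100, 200))
        k = 6
        breaks = rs.jenks_breaks(vals, k)

        def ssd_of_partition(cuts):
            # cuts: k-1 indices splitting the sorted array
            parts = np.split(vals, cuts)
            return sum(((p - p.mean()) ** 2).sum() for p in parts if len(p))

        # recover the DP's cut indices from its break values
        dp_cuts = [np.searchsorted(vals, b, side="right")
                   for b in breaks[1:-1]]
        dp_ssd = ssd_of_partition(dp_cuts)
        for _ in range(1000):
            cuts = np.sort(rng.choice(np.arange(1, 200), k - 1,
                                      replace=False))
            assert dp_ssd <= ssd_of_partition(cuts) + 1e-9

    def test_insufficient_classes_rejected(self):
        with pytest.raises(ValueError):
            rs.jenks_breaks([1, 2, 3], 1)
        with pytest.raises(ValueError):
            rs.jenks_breaks([1, 1, 1, 1], 3)


class TestClassification:
    @pytest.mark.parametrize("tri_value,expected", [
        (0.0, 1), (1.0, 1), (13.0, 1), (25.0, 2), (37.5, 2), (50.0, 3),
        (69.0, 3), (88.0, 4), (100.0, 4), (139.0, 5), (184.5, 5),
        (230.0, 6), (250.0, 6), (271.0, 6), (400.0, 6),
    ])
    def test_tri_bins_exhaustive(self, tri_value, expected):
        """Every ruggedness bin edge and midpoint maps to its printed
        resistance; out-of-range extremes take the end classes."""
        layer = rs.classify_continuous(Grid(np.full((3, 3), tri_value)),
                                       rs.TRI_SCHEME)
        assert np.all(layer.grid.data == expected)

    @pytest.mark.parametrize("name,age,expected", [
        ("mature_forest", 120.0, 1), ("mature_forest", 80.0, 1),
        ("mature_forest", 40.0, 3), ("regenerating_forest", 40.0, 3),
        ("regenerating_forest", 10.0, 3), ("regenerating_forest", 75.0, 3),
        ("mature_forest", 5.0, 1),  # early-seral open ground
        ("bryoid_shrub_herb", 120.0, 1), ("barren_rock", 120.0, 1),
        ("snow_ice", 120.0, 6), ("snow_ice", 40.0, 6),
    ])
    def test_landcover_mapping(self, name, age, expected):
        codes = np.full((3, 3), w.synthetic.LANDCOVER_CODES[name])
        layer = rs.classify_landcover(Grid(codes),
                                      Grid(np.full((3, 3), age)))
        assert np.all(layer.grid.data[~layer.grid.nodata_mask] == expected)

    def test_water_cells_nodata_on_landcover_layer(self):
        codes = np.array([[0, 1], [1, 0]])
        layer = rs.classify_landcover(Grid(codes), Grid(np.full((2, 2), 99.0)))
        assert layer.grid.nodata_mask[0, 0] and layer.grid.nodata_mask[1, 1]
        assert not layer.grid.nodata_mask[0, 1]

    def test_unknown_category_named_in_error(self):
        with pytest.raises(ValueError, match="7"):
            rs.classify_landcover(Grid(np.full((2, 2), 7)),
                                  Grid(np.full((2, 2), 50.0)))

    @pytest.mark.parametrize("dist_m,expected", [
        (0.0, 3), (500.0, 3), (999.0, 3), (1000.0, 5), (2000.0, 5),
        (3000.0, 6), (3001.0, 6), (10_000.0, 6),
    ])
    def test_water_distance_bins(self, dist_m, expected):
        water = Grid(np.ones((3, 3), dtype=bool))
        layer = rs.classify_water(Grid(np.full((3, 3), dist_m)), water)
        assert np.all(layer.grid.data == expected)

    def test_layer_domains_exclusive(self, elevation, landscape_cfg, land):
        """No cell carries both a landcover and a water resistance."""
        cover, age = w.generate_landcover(elevation, landscape_cfg)
        lc = rs.classify_landcover(cover.like(cover.data.astype(int)), age)
        water = land.like(~(land.data > 0.5))
        wl = rs.classify_water(rs.distance_to_shore(water), water)
        both = ~lc.grid.nodata_mask & ~wl.grid.nodata_mask
        assert not both.any()


class TestDistanceToShore:
    def test_cardinal_and_diagonal_adjacency(self):
        water = np.ones((3, 3), dtype=bool)
        water[1, 1] = False  # single land cell
        d = rs.distance_to_shore(Grid(water, cell_size=150.0))
        assert d.data[1, 1] == 0.0
        assert d.data[0, 1] == pytest.approx(150.0)
        assert d.data[0, 0] == pytest.approx(150.0 * np.sqrt(2))

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(3)
        water = rng.random((20, 20)) < 0.6
        water[5, 5] = False  # ensure land exists
        g = Grid(water, cell_size=150.0)
        d = rs.distance_to_shore(g)
        land_rc = np.argwhere(~water)
        for r in range(20):
            for c in range(20):
                if water[r, c]:
                    brute = np.min(np.hypot(land_rc[:, 0] - r,
                                            land_rc[:, 1] - c)) * 150.0
                    assert d.data[r, c] == pytest.approx(brute)

    def test_all_water_rejected(self):
        with pytest.raises(ValueError):
            rs.distance_to_shore(Grid(np.ones((4, 4), dtype=bool)))


class TestCombine:
    def _layers(self, tri_vals, lc_vals, water_vals, land_mask):
        tri = rs.ResistanceLayer(Grid(tri_vals.astype(float)), "tri")
        lc = rs.ResistanceLayer(
            Grid(lc_vals.astype(float), nodata_mask=~land_mask), "landcover")
        wl = rs.ResistanceLayer(
            Grid(water_vals.astype(float), nodata_mask=land_mask), "water")
        return tri, lc, wl

    def test_full_scale_after_rescaling(self, cumulative):
        vals = cumulative.grid.valid_values()
        assert vals.min() == pytest.approx(1.0)
        assert vals.max() == pytest.approx(10.0)

    def test_uniform_landscape_maps_to_one(self):
        land = np.ones((4, 4), dtype=bool)
        tri, lc, wl = self._layers(np.full((4, 4), 2), np.full((4, 4), 3),
                                   np.full((4, 4), 5), land)
        out = rs.combine_layers(tri, lc, wl)
        assert np.all(out.grid.data == 1.0)

    def test_rescale_monotone_and_order_invariant(self):
        rng = np.random.default_rng(1)
        land = rng.random((6, 6)) < 0.7
        tri_v = rng.integers(1, 7, (6, 6))
        lc_v = rng.integers(1, 7, (6, 6))
        w_v = rng.integers(3, 7, (6, 6))
        tri, lc, wl = self._layers(tri_v, lc_v, w_v, land)
        out = rs.combine_layers(tri, lc, wl)
        raw = out.raw.data
        fin = out.grid.data
        ok = ~out.grid.nodata_mask
        order_raw = np.argsort(raw[ok], kind="stable")
        assert np.all(np.diff(fin[ok][order_raw]) >= -1e-12)
        # summation order does not matter: same sum on land/water domains
        expected_raw = np.where(land, tri_v + lc_v, tri_v + w_v)
        assert np.allclose(raw[ok], expected_raw[ok])

    def test_land_and_water_cells_sum_their_own_layers(self):
        land = np.array([[True, False]])
        tri, lc, wl = self._layers(np.array([[2, 2]]), np.array([[3, 3]]),
                                   np.array([[5, 5]]), land)
        out = rs.combine_layers(tri, lc, wl)
        assert out.raw.data[0, 0] == 5.0   # tri + landcover
        assert out.raw.data[0, 1] == 7.0   # tri + water


class TestClip:
    def test_zero_buffer_clips_exactly(self):
        g = Grid(np.arange(100.0).reshape(10, 10), cell_size=100.0,
                 origin=(0.0, 1000.0))
        poly = box(0, 500, 500, 1000)  # upper-left 5x5 block
        out = rs.clip_with_buffer(g, poly, buffer_m=0.0)
        assert out.n_valid == 25
        assert out.shape == (5, 5)

    def test_buffer_distance_inclusion(self):
        """A cell centre 9.9 km outside the boundary survives a 10 km
        buffer; one 10.1 km outside does not."""
        g = Grid(np.zeros((1, 3)), cell_size=200.0, origin=(0.0, 200.0))
        # centres at x = 100, 300, 500
        keep_centre = Point(100, 100)
        poly = keep_centre.buffer(1.0)
        out = rs.clip_with_buffer(g, poly, buffer_m=199.0 + 1.0)
        assert not out.nodata_mask[0, 0]
        assert not out.nodata_mask[0, 1]   # 200 m away < 200 m buffer zone
        assert out.shape[1] == 2           # third centre (400 m) cropped

    def test_valid_count_non_increasing(self, cumulative):
        g = cumulative.grid
        poly = box(*(0, -9000, 4000, 0))
        out = rs.clip_with_buffer(g, poly, buffer_m=1000.0)
        assert out.n_valid <= g.n_valid

    def test_empty_intersection_rejected(self):
        g = Grid(np.zeros((3, 3)), cell_size=100.0)
        with pytest.raises(ValueError):
            rs.clip_with_buffer(g, box(10_000, 10_000, 10_100, 10_100),
                                buffer_m=10.0)
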