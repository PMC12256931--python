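"""Generators: determinism, limits, and the constraints of each artifact."""

import numpy as np
import pandas as pd
import pytest

import waveways as w
from waveways import resistance as rs
from waveways.synthetic import (_truncated_lognormal_lengths,
                                generate_land_mask)


class TestElevation:
    def test_flat_limit_has_zero_ruggedness(self, landscape_cfg):
        cfg = w.LandscapeConfig(extent_m=(3000, 3000), seed=1,
                                ruggedness_scale=0.0)
        elev = w.generate_elevation(cfg)
        assert np.all(elev.data == 0)
        tri = rs.terrain_ruggedness_index(elev)
        assert np.all(tri.data == 0)

    def test_same_seed_bit_identical(self, landscape_cfg):
        a = w.generate_elevation(landscape_cfg)
        b = w.generate_elevation(landscape_cfg)
        assert np.array_equal(a.data, b.data)

    def test_different_seed_differs(self, landscape_cfg, elevation):
        other = w.LandscapeConfig(**{**landscape_cfg.__dict__, "seed": 8})
        assert not np.array_equal(w.generate_elevation(other).data,
                                  elevation.data)

    def test_range_spans_ruggedness_scale(self, elevation, landscape_cfg):
        assert elevation.data.min() == 0.0
        assert elevation.data.max() == pytest.approx(
            landscape_cfg.ruggedness_scale)

    def test_tri_occupies_multiple_resistance_classes(self):
        """A 40x40, 500 m-relief terrain should produce TRI values falling
        in at least 3 of the six ruggedness classes."""
        cfg = w.LandscapeConfig(extent_m=(6000, 6000), seed=7,
                                ruggedness_scale=500.0)
        tri = rs.terrain_ruggedness_index(w.generate_elevation(cfg))
        classes = np.unique(rs.TRI_SCHEME.classify(tri.data))
        assert len(classes) >= 3

    def test_invalid_extent_rejected(self):
        with pytest.raises(ValueError):
            w.LandscapeConfig(extent_m=(-100, 100))
        with pytest.raises(ValueError):
            w.LandscapeConfig(extent_m=(1000, 1000), cell_size_m=150)


class TestLandcover:
    def test_zero_fractions_leave_three_classes(self, elevation):
        cfg = w.LandscapeConfig(seed=7, regen_fraction=0.0,
                                snowice_fraction=0.0)
        cover, _ = w.generate_landcover(elevation, cfg)
        land = generate_land_mask(elevation, cfg).data
        present = set(np.unique(cover.data[land]))
        assert present <= {w.synthetic.LANDCOVER_CODES["mature_forest"],
                           w.synthetic.LANDCOVER_CODES["bryoid_shrub_herb"],
                           w.synthetic.LANDCOVER_CODES["barren_rock"]}

    def test_snowice_restricted_to_top_elevation_quantile(
            self, elevation, landscape_cfg):
        cfg = w.LandscapeConfig(**{**landscape_cfg.__dict__,
                                   "snowice_fraction": 0.1})
        cover, _ = w.generate_landcover(elevation, cfg)
        land = generate_land_mask(elevation, cfg).data
        snow = cover.data == w.synthetic.LANDCOVER_CODES["snow_ice"]
        assert snow.any()
        thr = np.quantile(elevation.data[land], 0.9)
        assert elevation.data[snow].min() >= thr - 1e-9

    def test_water_cells_are_water_class(self, elevation, landscape_cfg,
                                         land):
        cover, _ = w.generate_landcover(elevation, landscape_cfg)
        water = ~land.data.astype(bool)
        assert np.all(cover.data[water] ==
                      w.synthetic.LANDCOVER_CODES["water/none"])

    def test_regen_fraction_approximate(self, elevation, landscape_cfg):
        cover, age = w.generate_landcover(elevation, landscape_cfg)
        land = generate_land_mask(elevation, landscape_cfg).data
        regen = cover.data == w.synthetic.LANDCOVER_CODES[
            "regenerating_forest"]
        frac = regen.sum() / land.sum()
        assert abs(frac - landscape_cfg.regen_fraction) < 0.08
        assert np.all((age.data[regen] >= 10) & (age.data[regen] <= 75))

    def test_fraction_sum_over_one_rejected(self):
        with pytest.raises(ValueError):
            w.LandscapeConfig(regen_fraction=0.7, snowice_fraction=0.5)


class TestHydrology:
    def test_streams_reach_coast_and_stay_on_land(self, elevation,
                                                  landscape_cfg, land):
        net = w.generate_hydrology(elevation, landscape_cfg)
        assert len(net.streams) == landscape_cfg.n_streams
        grid = elevation
        for geom in net.reaches["geometry"]:
            for x, y in geom.coords:
                r, c = grid.xy_to_rowcol(x, y)
                assert land.data[int(r), int(c)]

    def test_reach_length_truncation_bounds(self):
        rng = np.random.default_rng(0)
        lengths = _truncated_lognormal_lengths(rng, 10_000)
        assert lengths.min() >= 19.0
        assert lengths.max() <= 11_300.0
        # truncated mean calibrated to the observed 1.7 km average
        assert abs(lengths.mean() - 1700) < 100

    def test_multiple_species_share_watershed_code(self, elevation):
        cfg = w.LandscapeConfig(seed=11, n_streams=8, reaches_per_stream=3)
        elev = w.generate_elevation(cfg)
        net = w.generate_hydrology(elev, cfg)
        multi = net.reaches.groupby("watershed_code")["species"].nunique()
        assert (multi >= 2).any()
        # distinct records per (stream, species)
        assert not net.reaches.duplicated(
            ["watershed_code", "species"]).any()

    def test_all_water_raises(self):
        cfg = w.LandscapeConfig(seed=2, land_fraction=0.0)
        elev = w.generate_elevation(cfg)
        with pytest.raises(ValueError):
            w.generate_hydrology(elev, cfg)


class TestSnagSites:
    def test_pair_counts(self, land):
        cfg = w.LandscapeConfig(extent_m=(30000, 30000), seed=3)
        sites = w.generate_snag_sites(cfg, 66)
        assert len(sites) == 66
        assert sites.n_pairs == 2145
        two = w.generate_snag_sites(cfg, 2)
        assert two.n_pairs == 1

    def test_sites_on_land(self, landscape_cfg, land):
        sites = w.generate_snag_sites(landscape_cfg, 20, land=land)
        for x, y in sites.xy:
            r, c = land.xy_to_rowcol(x, y)
            assert land.data[int(r), int(c)]

    def test_too_many_sites_rejected(self, landscape_cfg, land):
        with pytest.raises(ValueError):
            w.generate_snag_sites(landscape_cfg, land.data.sum() + 1,
                                  land=land)

    def test_deterministic(self, landscape_cfg, land):
        a = w.generate_snag_sites(landscape_cfg, 15, land=land)
        b = w.generate_snag_sites(landscape_cfg, 15, land=land)
        assert np.array_equal(a.xy, b.xy)


class TestDetections:
    def test_zero_probability_gives_empty_table(self, landscape_cfg, land):
        sites = w.generate_snag_sites(landscape_cfg, 10, land=land)
        model = w.DetectionModel(n_individuals={"black": 5},
                                 baseline_detection_prob=0.0)
        det = w.simulate_detections(sites, model, seed=1, land=land)
        assert len(det) == 0

    def test_saturated_limit_detects_everyone_everywhere(self, landscape_cfg,
                                                         land):
        sites = w.generate_snag_sites(landscape_cfg, 5, land=land)
        model = w.DetectionModel(n_individuals={"black": 3},
                                 home_range_sigma_m=np.inf,
                                 baseline_detection_prob=1.0, n_years=2)
        det = w.simulate_detections(sites, model, seed=1, land=land)
        # 3 individuals x 5 sites x 2 years x 2 sessions
        assert len(det) == 3 * 5 * 2 * 2

    def test_multi_site_individuals_occur(self, landscape_cfg, land):
        """With the study-scale kernel (sigma 5170 m, p0 0.3) a fair share
        of individuals should be caught at 2+ sites within a season."""
        sites = w.generate_snag_sites(landscape_cfg, 20, land=land)
        model = w.DetectionModel(n_individuals={"black": 50},
                                 home_range_sigma_m=5170.0,
                                 baseline_detection_prob=0.3, n_years=1)
        det = w.simulate_detections(sites, model, seed=4, land=land)
        per_ind = det.groupby(["individual_id", "year"])["site_id"].nunique()
        assert (per_ind >= 2).mean() > 0


class TestTransits:
    def _pairs(self, n=2145, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"G": rng.lognormal(0, 1, n),
                             "distance_m": rng.uniform(1400, 102000, n)})

    def test_null_model_rate_half(self):
        pairs = self._pairs()
        model = w.TransitSimModel(beta0=0.0, beta_G=0.0, beta_d=0.0)
        out = w.simulate_transits(pairs, model, seed=5)
        rate = out["transited"].mean()
        se = 0.5 / np.sqrt(len(pairs))
        assert abs(rate - 0.5) < 3 * se

    def test_base_rate_matches_analytic_mean(self):
        """Empirical transit rate matches the mean of the simulated
        Bernoulli probabilities (computed directly from the linear
        predictor) within Monte-Carlo error."""
        from scipy.special import expit
        pairs = self._pairs(seed=3)
        model = w.TransitSimModel()  # printed odds-ratio anchored slopes
        g = (pairs["G"] - pairs["G"].mean()) / pairs["G"].std()
        d = (pairs["distance_m"] - pairs["distance_m"].mean()) / \
            pairs["distance_m"].std()
        p = expit(model.beta0 + model.beta_G * g + model.beta_d * d)
        rates = [w.simulate_transits(pairs, model, seed=s)["transited"].mean()
                 for s in range(20)]
        se = np.sqrt((p * (1 - p)).sum()) / len(pairs)
        assert abs(np.mean(rates) - p.mean()) < 3 * se / np.sqrt(20)

    def test_calibrated_intercept_hits_sparse_base_rate(self):
        pairs = self._pairs(seed=3)
        model = w.TransitSimModel()
        b0 = w.calibrate_intercept(pairs, model, 54 / 2145)
        from scipy.special import expit
        g = np.asarray(pairs["G"], dtype=float)
        d = np.asarray(pairs["distance_m"], dtype=float)
        g = (g - g.mean()) / g.std()
        d = (d - d.mean()) / d.std()
        assert expit(b0 + model.beta_G * g + model.beta_d * d).mean() == \
            pytest.approx(54 / 2145, rel=1e-6)

    def test_distance_effect_monotone_across_quartiles(self):
        pairs = self._pairs(seed=1)
        model = w.TransitSimModel(beta0=0.0, beta_G=0.0, beta_d=-3.0)
        out = w.simulate_transits(pairs, model, seed=9)
        out["q"] = pd.qcut(out["distance_m"], 4, labels=False)
        rates = out.groupby("q")["transited"].mean().to_numpy()
        assert np.all(np.diff(rates) < 0)

    def test_zero_variance_predictor_rejected(self):
        pairs = pd.DataFrame({"G": np.ones(10),
                              "distance_m": np.arange(10.0)})
        with pytest.raises(ValueError):
            w.simulate_transits(pairs, w.TransitSimModel(), seed=0)

    def test_deterministic_per_seed(self):
        pairs = self._pairs(100)
        a = w.simulate_transits(pairs, w.TransitSimModel(), seed=3)
        b = w.simulate_transits(pairs, w.TransitSimModel(), seed=3)
        assert a["transited"].equals(b["transited"])
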