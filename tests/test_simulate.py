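import numpy as np
import pandas as pd
import pytest

import phenosync as ps
from phenosync.config import SimulationConfig
from phenosync.errors import ConfigError, InputError
from phenosync.evi2 import period_midpoint
from phenosync.simulate import (generate_breeding, generate_cloud,
                                generate_landscape, generate_observations,
                                generate_true_greenup, seasonal_evi2,
                                simulate_dataset)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"grid_rows": 1}, {"year_sd": -1}, {"evi_base": 0.0},
        {"senescence_day": 100.0, "mean_greenup": 110.0}, {"occupancy": 0.0},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)

    def test_dict_roundtrip(self, small_cfg):
        assert SimulationConfig.from_dict(small_cfg.to_dict()) == small_cfg


class TestLandscape:
    def test_seeded_reproducibility(self, small_cfg):
        a = generate_landscape(small_cfg, np.random.default_rng(3))
        b = generate_landscape(small_cfg, np.random.default_rng(3))
        assert a.grid.to_csv() == b.grid.to_csv()
        assert a.nestboxes.to_csv() == b.nestboxes.to_csv()
        assert a.habitat.to_csv() == b.habitat.to_csv()

    def test_proportions_simplex(self, small_bundle):
        hab = small_bundle.landscape.habitat
        canopy = hab[[c for c in hab if c.startswith("canopy_")]]
        under = hab[[c for c in hab if c.startswith("under_")]]
        for layer in (canopy, under):
            assert (layer.to_numpy() >= 0).all()
            assert (layer.sum(axis=1) <= 1 + 1e-9).all()

    def test_border_less_wooded_than_interior(self, small_bundle):
        grid = small_bundle.landscape.grid
        ring = np.minimum.reduce([grid.row, grid.col,
                                  grid.row.max() - grid.row,
                                  grid.col.max() - grid.col])
        assert grid.woodland_fraction[ring == 0].mean() < \
            grid.woodland_fraction[ring >= 2].mean() - 0.2

    def test_boxes_in_woodland_pixels(self, small_bundle):
        grid = small_bundle.landscape.grid.set_index("pixel_id")
        wf = grid.loc[small_bundle.landscape.nestboxes.pixel_id,
                      "woodland_fraction"]
        assert (wf > 0.5).all()

    def test_zero_range_decorrelates_oak(self):
        """With no smoothing, neighbouring pixels' oak proportions are
        uncorrelated (Monte-Carlo over 20 seeds on a 20x20 grid)."""
        rs = []
        for seed in range(20):
            cfg = SimulationConfig(grid_rows=20, grid_cols=20, spatial_range=0.0,
                                   n_nestboxes=10, seed=seed)
            land = generate_landscape(cfg)
            oak = land.habitat.sort_values("pixel_id").canopy_oak.to_numpy()
            oak = oak.reshape(20, 20)
            a, b = oak[:, :-1].ravel(), oak[:, 1:].ravel()
            rs.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(rs)) < 0.15

    def test_positive_range_correlates_oak(self):
        cfg = SimulationConfig(grid_rows=20, grid_cols=20, spatial_range=600.0,
                               n_nestboxes=10, seed=0)
        land = generate_landscape(cfg)
        oak = land.habitat.sort_values("pixel_id").canopy_oak.to_numpy().reshape(20, 20)
        r = np.corrcoef(oak[:, :-1].ravel(), oak[:, 1:].ravel())[0, 1]
        assert r > 0.5

    def test_oak_density_tracks_canopy(self, small_bundle):
        boxes = small_bundle.landscape.nestboxes
        hab = small_bundle.landscape.habitat.set_index("pixel_id")
        oak_prop = hab.loc[boxes.pixel_id, "canopy_oak"].to_numpy()
        r = np.corrcoef(oak_prop, boxes.oak_density_75m)[0, 1]
        assert r > 0.7


class TestTrueGreenup:
    def test_degenerate_variance_collapses_to_mean(self):
        cfg = SimulationConfig(year_sd=0, spatial_sd=0, greenup_noise_sd=0,
                               n_nestboxes=10)
        tr = generate_true_greenup(cfg, np.random.default_rng(0))
        np.testing.assert_allclose(tr.dates, cfg.mean_greenup)

    def test_year_mean_sd_calibrated(self):
        cfg = SimulationConfig(n_years=200, n_nestboxes=10)
        tr = generate_true_greenup(cfg, np.random.default_rng(1))
        assert tr.year_means.std(ddof=1) == pytest.approx(cfg.year_sd, rel=0.15)

    def test_seeded_determinism(self, small_cfg):
        a = generate_true_greenup(small_cfg, np.random.default_rng(5))
        b = generate_true_greenup(small_cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(a.dates, b.dates)


class TestObservations:
    def _mini_cfg(self, **kw):
        base = dict(grid_rows=2, grid_cols=2, n_years=1, n_nestboxes=4, seed=0)
        base.update(kw)
        return SimulationConfig(**base)

    def test_full_cloud_no_clear_looks(self):
        cfg = self._mini_cfg()
        tr = generate_true_greenup(cfg, np.random.default_rng(0))
        cloud = generate_cloud(cfg, np.random.default_rng(0))
        cloud["cloud_fraction"] = 100.0
        obs = generate_observations(cfg, tr, cloud, np.random.default_rng(0))
        assert (obs.cloudy == 1).all()

    def test_cloud_out_of_range_rejected(self):
        cfg = self._mini_cfg()
        tr = generate_true_greenup(cfg, np.random.default_rng(0))
        cloud = generate_cloud(cfg, np.random.default_rng(0))
        cloud.loc[0, "cloud_fraction"] = 130.0
        with pytest.raises(InputError):
            generate_observations(cfg, tr, cloud, np.random.default_rng(0))

    def test_noiseless_period_means_match_curve(self):
        cfg = self._mini_cfg(obs_noise_sd=0.0)
        tr = generate_true_greenup(cfg, np.random.default_rng(1))
        cloud = generate_cloud(cfg, np.random.default_rng(1))
        cloud["cloud_fraction"] = 0.0
        obs = generate_observations(cfg, tr, cloud, np.random.default_rng(1))
        series = ps.aggregate_periods(obs)
        for pixel in range(4):
            sub = series[series.pixel_id == pixel]
            expected = seasonal_evi2(period_midpoint(sub.period.to_numpy()),
                                     tr.dates[0, pixel], cfg)
            np.testing.assert_allclose(sub.evi2.to_numpy(), expected, atol=1e-9)

    def test_mean_clear_looks_under_three_quarters_cloud(self):
        cfg = self._mini_cfg(n_years=3)
        tr = generate_true_greenup(cfg, np.random.default_rng(2))
        cloud = generate_cloud(cfg, np.random.default_rng(2))
        cloud["cloud_fraction"] = 75.0
        obs = generate_observations(cfg, tr, cloud, np.random.default_rng(2))
        series = ps.aggregate_periods(obs)
        # Binomial(16, 0.25): about 4 clear looks per pixel-period
        assert series.n_clear.mean() == pytest.approx(4.0, abs=0.15)

    def test_thinning_identity(self, small_bundle, small_cfg):
        obs = small_bundle.observations
        obs = obs.assign(doy=pd.to_datetime(obs.date).dt.dayofyear)
        per = obs.groupby(["pixel_id", pd.to_datetime(obs.date).dt.year,
                           (obs.doy - 1) // 8]).size()
        assert (per == small_cfg.looks_per_period).all()


class TestBreeding:
    def test_all_effects_off_constant_laying(self):
        cfg = SimulationConfig(
            grid_rows=4, grid_cols=4, n_years=2, n_nestboxes=40, seed=3,
            beta_within=0, beta_between=0, beta_altitude=0, beta_edge=0,
            beta_oak=0, oak_coupling_gain=0, residual_sd=0, year_re_sd=0,
            box_re_sd=0)
        land = generate_landscape(cfg, np.random.default_rng(0))
        tr = generate_true_greenup(cfg, np.random.default_rng(1))
        breeding, _ = generate_breeding(cfg, land, tr, np.random.default_rng(2))
        first, _ = ps.filter_first_broods(breeding)
        gt = first[first.species == "great_tit"]
        bt = first[first.species == "blue_tit"]
        assert (gt.laying_day == round(cfg.mean_laying)).all()
        assert (bt.laying_day == round(cfg.mean_laying + cfg.blue_tit_offset)).all()

    def test_laying_recoverable_from_observation(self, small_bundle):
        b = small_bundle.breeding
        inferred = ps.infer_laying_date(b.obs_day.to_numpy(),
                                        b.eggs_observed.to_numpy())
        np.testing.assert_array_equal(inferred, b.laying_day.to_numpy())

    def test_hatch_after_laying(self, small_bundle):
        b = small_bundle.breeding
        assert (b.hatch_day > b.laying_day).all()

    def test_oak_coupling_raises_synchrony_in_oak_rich_pixels(self):
        """Construction check: with positive coupling gain, the true
        laying/green-up correlation is higher where oak is dense."""
        diffs = []
        for seed in range(10):
            cfg = SimulationConfig(grid_rows=8, grid_cols=8, n_years=13,
                                   n_nestboxes=400, seed=seed,
                                   oak_coupling_gain=25.0)
            b = simulate_dataset(cfg, skip_observations=True)
            tab = b.breeding.merge(b.landscape.nestboxes[["box_id", "pixel_id",
                                                          "oak_density_75m"]],
                                   on="box_id")
            tab, _ = ps.filter_first_broods(tab)
            truth = b.greenup.as_frame().set_index(["pixel_id", "year"])
            tab["greenup"] = truth.true_greenup.reindex(
                pd.MultiIndex.from_frame(tab[["pixel_id", "year"]])).to_numpy()
            med = tab.oak_density_75m.median()
            r_rich = annual_r(tab[tab.oak_density_75m > med])
            r_poor = annual_r(tab[tab.oak_density_75m <= med])
            diffs.append(r_rich - r_poor)
        assert sum(d > 0 for d in diffs) >= 9

    def test_halffall_tracks_annual_greenup(self):
        cfg = SimulationConfig(n_years=60, n_nestboxes=10, seed=5)
        land = generate_landscape(cfg, np.random.default_rng(0))
        tr = generate_true_greenup(cfg, np.random.default_rng(1))
        _, halffall = generate_breeding(cfg, land, tr, np.random.default_rng(2))
        wood = land.grid.woodland_fraction.to_numpy() > 0.5
        gbar = tr.dates[:, wood].mean(axis=1)
        slope = np.polyfit(gbar, halffall.halffall_day, 1)[0]
        assert slope == pytest.approx(cfg.halffall_slope, abs=0.25)


def annual_r(tab):
    from phenosync.cloudscan import annual_synchrony_series

    return annual_synchrony_series(tab).mean()


class TestBundle:
    def test_seeded_determinism_end_to_end(self, small_cfg, small_bundle):
        again = simulate_dataset(small_cfg)
        assert again.breeding.to_csv() == small_bundle.breeding.to_csv()
        assert again.observations.to_csv() == small_bundle.observations.to_csv()
        assert again.cloud.to_csv() == small_bundle.cloud.to_csv()

    def test_truth_json_contains_betas(self, small_bundle):
        import json

        truth = json.loads(small_bundle.truth_json())
        assert truth["true_betas"]["within"] == small_bundle.config.beta_within
        assert len(truth["annual_mean_greenup"]) == small_bundle.config.n_years
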