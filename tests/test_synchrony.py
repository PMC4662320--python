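import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenosync.errors import UndefinedStatisticError
from phenosync.synchrony import (compare_species_synchrony, habitat_overlay,
                                 pixel_synchrony, synchrony_habitat_regression)


def _gmap(pixel_ids, years, dates):
    return pd.DataFrame({"pixel_id": np.repeat(pixel_ids, len(years)),
                         "year": np.tile(years, len(pixel_ids)),
                         "greenup_day": np.asarray(dates, float).ravel(),
                         "converged": True})


def _grid(pixel_ids, woodland=0.9):
    return pd.DataFrame({"pixel_id": pixel_ids, "woodland_fraction": woodland})


class TestPixelSynchrony:
    def test_perfect_tracking_gives_r_one(self):
        years = np.arange(2001, 2011)
        g = 105 + np.sin(years) * 6
        gmap = _gmap([0], years, g)
        table = pd.DataFrame({"pixel_id": 0, "year": years, "species": "great_tit",
                              "laying_day": g - 30})
        sync = pixel_synchrony(table, gmap, _grid([0]))
        assert sync.r.iloc[0] == pytest.approx(1.0)
        assert sync.included.iloc[0]

    def test_min_years_exclusion(self):
        years = np.arange(2001, 2005)  # 4 year-points < default 6
        gmap = _gmap([0], years, 105 + np.arange(4.0))
        table = pd.DataFrame({"pixel_id": 0, "year": years,
                              "laying_day": [20.0, 22, 21, 25]})
        sync = pixel_synchrony(table, gmap, _grid([0]), min_years=6)
        assert not sync.included.iloc[0]
        assert sync.exclude_reason.iloc[0] == "below_min_years"
        assert np.isfinite(sync.r.iloc[0])  # r still computed from 4 points

    def test_hand_computed_r(self):
        rng = np.random.default_rng(5)
        years = np.arange(2001, 2010)
        g = rng.normal(108, 5, 9)
        lay = rng.normal(21, 3, 9)
        gmap = _gmap([0], years, g)
        table = pd.DataFrame({"pixel_id": 0, "year": years, "laying_day": lay})
        sync = pixel_synchrony(table, gmap, _grid([0]))
        assert sync.r.iloc[0] == pytest.approx(stats.pearsonr(lay, g)[0])
        assert sync.n_years.iloc[0] == 9 and sync.n_attempts.iloc[0] == 9

    def test_non_woodland_pixels_absent(self):
        years = np.arange(2001, 2011)
        gmap = _gmap([0, 1], years, np.tile(105 + np.arange(10.0), 2))
        table = pd.DataFrame({"pixel_id": np.repeat([0, 1], 10),
                              "year": np.tile(years, 2),
                              "laying_day": np.tile(np.arange(20.0, 30), 2)})
        grid = pd.DataFrame({"pixel_id": [0, 1], "woodland_fraction": [0.9, 0.3]})
        sync = pixel_synchrony(table, gmap, grid)
        assert sync.pixel_id.tolist() == [0]

    def test_location_shift_invariance(self, truth_table, truth_greenup_map,
                                       small_bundle):
        """A common shift of all laying dates and all green-up dates leaves
        every pixel correlation unchanged (Pearson location invariance)."""
        sp = truth_table[truth_table.species == "great_tit"]
        grid = small_bundle.landscape.grid
        base = pixel_synchrony(sp, truth_greenup_map, grid)
        sp2 = sp.copy()
        sp2["laying_day"] += 9.0
        gmap2 = truth_greenup_map.copy()
        gmap2["greenup_day"] += 9.0
        shifted = pixel_synchrony(sp2, gmap2, grid)
        np.testing.assert_allclose(base.r, shifted.r, atol=1e-10)


class TestHabitatOverlay:
    def test_wholly_inside_one_compartment(self):
        overlaps = pd.DataFrame({"compartment_id": [1], "pixel_id": [0],
                                 "area": [57600.0]})
        props = pd.DataFrame({"compartment_id": [1], "canopy_oak": [0.8]})
        out = habitat_overlay(overlaps, props)
        assert out.canopy_oak.iloc[0] == pytest.approx(0.8)

    def test_fifty_fifty_split(self):
        overlaps = pd.DataFrame({"compartment_id": [1, 2], "pixel_id": 0,
                                 "area": [100.0, 100.0]})
        props = pd.DataFrame({"compartment_id": [1, 2], "canopy_oak": [0.8, 0.2]})
        assert habitat_overlay(overlaps, props).canopy_oak.iloc[0] == pytest.approx(0.5)

    def test_quarter_split(self):
        overlaps = pd.DataFrame({"compartment_id": [1, 2], "pixel_id": 0,
                                 "area": [25.0, 75.0]})
        props = pd.DataFrame({"compartment_id": [1, 2], "under_hazel": [0.4, 0.0]})
        assert habitat_overlay(overlaps, props).under_hazel.iloc[0] == pytest.approx(0.1)

    def test_mass_conservation(self, small_bundle):
        hab = habitat_overlay(small_bundle.landscape.overlaps,
                              small_bundle.landscape.compartment_props)
        props = small_bundle.landscape.compartment_props
        for col in ("canopy_oak", "under_hazel"):
            assert hab[col].max() <= props[col].max() + 1e-12
            assert hab[col].min() >= props[col].min() - 1e-12


class TestHabitatRegression:
    def _sync(self, oak, r, w=None):
        sync = pd.DataFrame({"pixel_id": np.arange(len(oak)), "r": r,
                             "n_years": 10, "included": True,
                             "n_attempts": w if w is not None else 10})
        hab = pd.DataFrame({"pixel_id": np.arange(len(oak)), "canopy_oak": oak})
        return sync, hab

    def test_exact_linear_relation(self):
        oak = np.linspace(0, 0.5, 12)
        sync, hab = self._sync(oak, 0.1 + 0.4 * oak)
        res = synchrony_habitat_regression(sync, hab, "canopy_oak")
        assert res["slope"] == pytest.approx(0.4, abs=1e-10)
        assert res["intercept"] == pytest.approx(0.1, abs=1e-10)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(2)
        oak = rng.uniform(0, 0.5, 15)
        r = 0.2 + 0.5 * oak + rng.normal(0, 0.05, 15)
        w = rng.integers(1, 30, 15)
        s1, h = self._sync(oak, r, w)
        s2, _ = self._sync(oak, r, 2 * w)
        r1 = synchrony_habitat_regression(s1, h, "canopy_oak")
        r2 = synchrony_habitat_regression(s2, h, "canopy_oak")
        assert r1["slope"] == pytest.approx(r2["slope"], abs=1e-12)
        assert r1["se"] == pytest.approx(r2["se"], abs=1e-12)

    def test_equal_weights_match_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        oak = rng.uniform(0, 0.5, 15)
        r = 0.2 + 0.5 * oak + rng.normal(0, 0.05, 15)
        sync, hab = self._sync(oak, r, np.full(15, 7))
        res = synchrony_habitat_regression(sync, hab, "canopy_oak")
        ols = sm.OLS(r, sm.add_constant(oak)).fit()
        assert res["slope"] == pytest.approx(ols.params[1], abs=1e-10)
        assert res["se"] == pytest.approx(ols.bse[1], abs=1e-10)

    def test_constant_habitat_undefined(self):
        sync, hab = self._sync(np.full(10, 0.3), np.linspace(0, 1, 10))
        with pytest.raises(UndefinedStatisticError):
            synchrony_habitat_regression(sync, hab, "canopy_oak")


class TestCompareSpecies:
    def _map(self, values):
        return pd.DataFrame({"pixel_id": np.arange(len(values)), "r": values,
                             "included": True})

    def test_identical_samples_t_zero(self):
        m = self._map([0.1, 0.4, 0.6, 0.3])
        out = compare_species_synchrony(m, m.copy())
        assert out["t"] == pytest.approx(0.0)
        assert out["paired_r"] == pytest.approx(1.0)

    def test_welch_hand_value(self):
        out = compare_species_synchrony(self._map([0.1, 0.2, 0.3]),
                                        self._map([0.4, 0.5, 0.6]))
        assert out["t"] == pytest.approx(-3.674234, abs=1e-5)
        assert out["df"] == pytest.approx(4.0, abs=1e-9)

    def test_zero_variance_flagged_degenerate(self):
        out = compare_species_synchrony(self._map([0.0] * 4), self._map([1.0] * 4))
        assert out["degenerate"]
        assert np.isinf(out["t"])
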