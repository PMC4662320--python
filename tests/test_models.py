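import numpy as np
import pandas as pd
import pytest

import phenosync as ps
from phenosync.errors import UndefinedStatisticError
from phenosync.models import (annual_correlation, annual_mean_greenup,
                              fit_breeding_lmm, partition_within_between,
                              phenology_residuals)


class TestAnnualCorrelation:
    def test_perfect_positive(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert annual_correlation(x, x)[0] == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.array([1.0, 2, 3, 4])
        assert annual_correlation(x, -2 * x + 7)[0] == pytest.approx(-1.0)

    def test_hand_value(self):
        # scipy.stats.pearsonr oracle for x={1,2,3,4}, y={1,3,2,5}
        r, p, n = annual_correlation([1, 2, 3, 4], [1, 3, 2, 5])
        assert r == pytest.approx(0.8315218, abs=1e-6)
        assert n == 4

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 10))
        r1 = annual_correlation(x, y)[0]
        r2 = annual_correlation(3 * x - 5, 0.1 * y + 2)[0]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_incomplete_pairs_dropped(self):
        x = [1, 2, 3, 4, np.nan]
        y = [1, 3, 2, 5, 9]
        assert annual_correlation(x, y)[2] == 4

    @pytest.mark.parametrize("x,y", [
        ([1, 2], [3, 4]),               # too few pairs
        ([1, 1, 1, 1], [1, 3, 2, 5]),   # zero variance
    ])
    def test_undefined(self, x, y):
        with pytest.raises(UndefinedStatisticError):
            annual_correlation(x, y)


class TestPartitionWithinBetween:
    def test_two_record_year(self):
        df = pd.DataFrame({"year": [2001, 2001], "greenup": [100.0, 104.0]})
        out = partition_within_between(df)
        assert out.greenup_between.tolist() == [102.0, 102.0]
        assert out.greenup_within.tolist() == [-2.0, 2.0]

    def test_constant_year_all_zero_within(self):
        df = pd.DataFrame({"year": 2001, "greenup": [110.0] * 5})
        assert (partition_within_between(df).greenup_within == 0).all()

    def test_reconstruction_identity(self, truth_table):
        out = partition_within_between(truth_table)
        err = (out.greenup_between + out.greenup_within - out.greenup).abs()
        assert err.max() < 1e-12

    def test_balanced_design_orthogonality(self):
        # equal group sizes make the two components empirically uncorrelated
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"year": np.repeat(np.arange(8), 25),
                           "greenup": rng.normal(110, 5, 200)})
        out = partition_within_between(df)
        r = np.corrcoef(out.greenup_within, out.greenup_between)[0, 1]
        assert abs(r) < 1e-10


class TestAnnualMeanGreenup:
    @pytest.fixture
    def gmap_and_grid(self):
        gmap = pd.DataFrame({
            "pixel_id": [0, 1, 2, 3, 4], "year": 2001,
            "greenup_day": [100.0, 110, 120, 999, np.nan],
            "converged": [True, True, True, False, True]})
        grid = pd.DataFrame({"pixel_id": [0, 1, 2, 3, 4],
                             "woodland_fraction": [0.9, 0.8, 0.7, 0.9, 0.9]})
        return gmap, grid

    def test_mean_over_qualifying(self, gmap_and_grid):
        gmap, grid = gmap_and_grid
        assert annual_mean_greenup(gmap, grid, 2001) == pytest.approx(110.0)

    def test_threshold_strictly_greater(self, gmap_and_grid):
        gmap, grid = gmap_and_grid
        grid.loc[0, "woodland_fraction"] = 0.5  # exactly at threshold: excluded
        assert annual_mean_greenup(gmap, grid, 2001) == pytest.approx(115.0)

    def test_no_qualifying_pixels(self, gmap_and_grid):
        gmap, grid = gmap_and_grid
        grid["woodland_fraction"] = 0.1
        with pytest.raises(UndefinedStatisticError):
            annual_mean_greenup(gmap, grid, 2001)


class TestBreedingLmm:
    def test_recovers_within_coefficient_from_truth(self, truth_table, small_cfg):
        sub = truth_table[truth_table.species == "blue_tit"]
        fit = fit_breeding_lmm(sub, covariates="full")
        # with oak coupling, the population-average within slope is
        # beta_within * (1 + gain * mean(oak_norm))
        oak_norm = sub.oak_density_75m / small_cfg.oak_density_scale
        expected = small_cfg.beta_within * (1 + small_cfg.oak_coupling_gain
                                            * oak_norm.mean())
        est, se = fit.params.greenup_within, fit.bse.greenup_within
        assert abs(est - expected) < 3 * se
        assert fit.converged

    def test_female_re_drops_unknown_females(self, truth_table):
        sub = truth_table[truth_table.species == "great_tit"]
        fit = fit_breeding_lmm(sub, covariates="minimal", female_re=True)
        assert fit.nobs == sub.female_id.notna().sum()
        assert "female" in fit.vcov

    def test_design_matches_request(self, truth_table):
        sub = truth_table[truth_table.species == "great_tit"]
        minimal = fit_breeding_lmm(sub, covariates="minimal")
        full = fit_breeding_lmm(sub, covariates="full")
        assert list(minimal.params.index) == ["intercept", "greenup_within",
                                              "greenup_between"]
        assert list(full.params.index) == ["intercept", "greenup_within",
                                           "greenup_between", "altitude",
                                           "edge_distance", "oak_density_75m"]

    def test_shift_invariance_at_common_covariance(self, truth_table):
        """A year-constant shift of green-up leaves the within coefficient
        untouched when year is the covariance grouping (exact GLS algebra)."""
        from phenosync.mixedlm import fit_mixed_lm

        sub = truth_table[truth_table.species == "great_tit"]

        def within_coef(df, theta=None):
            d = partition_within_between(df)
            X = pd.DataFrame({"intercept": 1.0, "w": d.greenup_within,
                              "b": d.greenup_between})
            kw = dict(theta0=theta, fixed_theta=True) if theta is not None else {}
            return fit_mixed_lm(d.laying_day.to_numpy(float), X,
                                {"year": d.year.to_numpy()}, **kw)

        base = within_coef(sub)
        shifted = sub.copy()
        year = shifted.year.unique()[1]
        shifted.loc[shifted.year == year, "greenup"] += 11.0
        refit = within_coef(shifted, theta=base.theta)
        same = within_coef(sub, theta=base.theta)
        assert abs(refit.params["w"] - same.params["w"]) < 1e-8


class TestPhenologyResiduals:
    def test_year_effects_removed(self, truth_table):
        sub = truth_table[truth_table.species == "great_tit"]
        resid = phenology_residuals(sub)
        per_year = resid.groupby(sub.loc[resid.index, "year"]).mean()
        # annual means of residuals are shrunk near zero
        assert per_year.abs().max() < 1.0
        assert len(resid) == len(sub)
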