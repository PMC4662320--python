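"""Reproducible validation experiments on synthetic data.

Each function runs one self-contained simulation experiment — green-up
recovery under cloud thinning, mixed-model coefficient recovery through the
full satellite pipeline, habitat-slope sign recovery, Mantel-test
calibration, window-scan signal planting — and returns plain numbers.  They
back both the test suite and ``scripts/acceptance.py``; problem sizes are
chosen so a full run stays in the minutes range on one core (see
docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import breeding as breeding_mod
from .cloudscan import enumerate_windows, scan_windows, window_mean_cloud
from .config import SimulationConfig
from .evi2 import aggregate_periods
from .greenup import extract_greenup_date, extract_greenup_map, fit_smooth_curve
from .mantel import mantel_correlogram
from .mixedlm import fit_mixed_lm
from .models import fit_breeding_lmm, partition_within_between
from .simulate import (generate_cloud, generate_observations,
                       generate_true_greenup, seasonal_evi2, simulate_dataset)
from .synchrony import habitat_regression_table, pixel_synchrony
from .weighting import PixelGrid, nestbox_greenup_table


def greenup_noiseless_error(inflection: float = 110.0) -> float:
    """|extracted - true| green-up day for a noise-free double-logistic curve."""
    cfg = SimulationConfig(n_nestboxes=4)
    mids = np.arange(4, 365, 8.0)
    y = seasonal_evi2(mids, inflection, cfg)
    fit = fit_smooth_curve(mids, y)
    return float(abs(extract_greenup_date(fit).greenup_day - inflection))


def _thinned_greenup_errors(seed: int, cloud_pct: float, grid: int = 5,
                            n_years: int = 4) -> np.ndarray:
    """Per-pixel-year |error| of green-up extraction at a flat cloud level."""
    cfg = SimulationConfig(grid_rows=grid, grid_cols=grid, n_years=n_years,
                           n_nestboxes=4, seed=seed)
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)]
    truth = generate_true_greenup(cfg, rngs[0])
    cloud = generate_cloud(cfg, rngs[1])
    cloud["cloud_fraction"] = float(cloud_pct)
    obs = generate_observations(cfg, truth, cloud, rngs[2], include_cloudy=False)
    gmap = extract_greenup_map(aggregate_periods(obs))
    merged = gmap[gmap.converged].merge(truth.as_frame(), on=["pixel_id", "year"])
    return (merged.greenup_day - merged.true_greenup).abs().to_numpy()


def greenup_recovery_median_error(seed: int, cloud_pct: float = 75.0) -> tuple:
    """Median |error| over 100 pixel-years at 75% cloud, per-look noise 0.02."""
    errs = _thinned_greenup_errors(seed, cloud_pct)
    return float(np.median(errs)), int(errs.size)


def cloud_mae_curve(seed: int, levels=(0, 50, 75, 90), n_seeds: int = 50) -> dict:
    """Mean green-up |error| per cloud level, averaged over seeds (3x3 grid,
    4 years per seed: same truth across levels, only the thinning differs)."""
    base = np.random.SeedSequence(seed).generate_state(n_seeds) % (2 ** 31)
    out = {}
    for level in levels:
        maes = [np.mean(_thinned_greenup_errors(int(s), level, grid=3))
                for s in base]
        out[level] = float(np.mean(maes))
    return out


def satellite_pipeline_table(config: SimulationConfig,
                             species: str = "great_tit") -> tuple:
    """Full chain on one synthetic dataset: observations -> EVI2 series ->
    green-up map -> nestbox weighting -> laying inference + filtering + join.

    Returns (analysis table for the species, truth bundle).
    """
    bundle = simulate_dataset(config, include_cloudy=False)
    series = aggregate_periods(bundle.observations)
    gmap = extract_greenup_map(series)
    grid = PixelGrid.from_dataframe(bundle.landscape.grid, config.pixel_size)
    nbg = nestbox_greenup_table(bundle.landscape.nestboxes, gmap, grid)
    records = bundle.breeding.drop(columns=["laying_day"])
    table, _, _ = breeding_mod.prepare_analysis_table(
        records, bundle.landscape.nestboxes, nbg)
    return table[table.species == species], bundle


def within_recovery_trial(seed: int) -> tuple:
    """One within-year coefficient recovery through the full satellite
    pipeline with oak coupling off: returns (estimate, SE, truth).

    The fit controls for altitude, edge distance and oak density: those
    habitat fields are spatially structured, as is green-up, so leaving them
    out lets per-landscape chance correlations between the fields confound
    the green-up coefficient.
    """
    cfg = SimulationConfig(seed=seed, oak_coupling_gain=0.0)
    table, bundle = satellite_pipeline_table(cfg)
    fit = fit_breeding_lmm(table, covariates="full")
    return (float(fit.params.greenup_within), float(fit.bse.greenup_within),
            cfg.beta_within)


def truth_based_table(config: SimulationConfig, species: str = "great_tit"):
    """Analysis table using the generator's true green-up (no satellite step)."""
    bundle = simulate_dataset(config, skip_observations=True)
    gmap = bundle.greenup.as_frame().rename(columns={"true_greenup": "greenup_day"})
    gmap["converged"] = True
    tab = bundle.breeding.merge(
        bundle.landscape.nestboxes[["box_id", "pixel_id", "altitude",
                                    "edge_distance", "oak_density_75m"]],
        on="box_id")
    tab, _ = breeding_mod.filter_first_broods(tab)
    truth = bundle.greenup.as_frame().set_index(["pixel_id", "year"])
    tab["greenup"] = truth.true_greenup.reindex(
        pd.MultiIndex.from_frame(tab[["pixel_id", "year"]])).to_numpy()
    return tab[tab.species == species], bundle


def oak_slope_trial(seed: int, gain: float) -> float:
    """Weighted synchrony-on-oak slope for one simulated woodland."""
    cfg = SimulationConfig(seed=seed, oak_coupling_gain=gain)
    tab, bundle = truth_based_table(cfg)
    gmap = bundle.greenup.as_frame().rename(columns={"true_greenup": "greenup_day"})
    gmap["converged"] = True
    sync = pixel_synchrony(tab, gmap, bundle.landscape.grid)
    reg = habitat_regression_table(sync, bundle.landscape.habitat,
                                   habitat_vars=["canopy_oak"])
    return float(reg.slope.iloc[0])


def mantel_exact_vs_montecarlo(seed: int, n_perm: int = 999) -> dict:
    """Monte-Carlo vs brute-force permutation p at n = 5 sites (120 perms)."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 1000, (5, 2))
    values = rng.normal(size=5)
    from scipy.spatial.distance import pdist

    edges = np.quantile(pdist(coords), [0, 0.5, 1.0])
    edges[-1] += 1e-6
    exact = mantel_correlogram(coords, values, class_edges=edges, method="exact")
    mc = mantel_correlogram(coords, values, class_edges=edges, n_perm=n_perm,
                            seed=seed)
    p_e = exact.table.p.to_numpy()
    p_m = mc.table.p.to_numpy()
    ok = np.isfinite(p_e)
    diff = np.abs(p_m[ok] - p_e[ok])
    bound = 3 * np.sqrt(p_e[ok] * (1 - p_e[ok]) / n_perm) + 1e-3
    return {"max_abs_diff": float(diff.max()), "bound": float(bound.max()),
            "within_bound": bool((diff <= bound).all())}


def mantel_type1_rate(seed: int, n_reps: int = 200, n_sites: int = 15,
                      n_perm: int = 199) -> float:
    """Fraction of distance classes called significant (p < 0.05) on
    spatially random values; should sit near the nominal 5%."""
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_reps):
        coords = rng.uniform(0, 1000, (n_sites, 2))
        values = rng.normal(size=n_sites)
        cg = mantel_correlogram(coords, values, n_classes=3, n_perm=n_perm,
                                seed=int(rng.integers(2 ** 31)))
        pvals.extend(cg.table.p.dropna().tolist())
    return float((np.asarray(pvals) < 0.05).mean())


def decomposition_checks(seed: int) -> dict:
    """Exactness of the within/between split and of the within-coefficient
    under a year-constant green-up shift (GLS at common covariance)."""
    cfg = SimulationConfig(grid_rows=6, grid_cols=6, n_years=6,
                           n_nestboxes=150, seed=seed)
    tab, _ = truth_based_table(cfg)
    part = partition_within_between(tab)
    identity_err = float((part.greenup_between + part.greenup_within
                          - part.greenup).abs().max())

    def within_coef(df, theta=None):
        d = partition_within_between(df)
        X = pd.DataFrame({"intercept": 1.0, "w": d.greenup_within,
                          "b": d.greenup_between})
        kw = dict(theta0=theta, fixed_theta=True) if theta is not None else {}
        return fit_mixed_lm(d.laying_day.to_numpy(float), X,
                            {"year": d.year.to_numpy()}, **kw)

    base = within_coef(tab)
    shifted = tab.copy()
    year = shifted.year.unique()[1]
    shifted.loc[shifted.year == year, "greenup"] += 11.0
    delta = abs(within_coef(shifted, base.theta).params["w"]
                - within_coef(tab, base.theta).params["w"])
    return {"identity_max_err": identity_err, "shift_delta": float(delta),
            "n": len(tab)}


def planted_window_scan(seed: int, target=(4, 6)) -> dict:
    """Synchrony constructed exactly linear in one window's mean cloudiness
    must rank that window first with |r| = 1."""
    cfg = SimulationConfig(seed=seed)
    cloud = generate_cloud(cfg, np.random.default_rng(seed))
    cloud = cloud[cloud.period <= 15]
    mc = window_mean_cloud(cloud, target)
    sync = pd.Series(2.0 - 0.02 * mc.to_numpy(), index=mc.index)
    scan = scan_windows(enumerate_windows(), cloud, sync)
    top = scan[scan.rank_abs == 1].iloc[0]
    return {"rank_of_target": float(scan.loc[(scan.start == target[0])
                                             & (scan.length == target[1]),
                                             "rank_abs"].iloc[0]),
            "top_abs_r": float(abs(top.r)),
            "top_window": (int(top.start), int(top.length)),
            "n_windows": len(scan)}
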