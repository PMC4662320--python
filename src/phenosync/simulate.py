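"""Synthetic woodland, satellite and breeding data with known ground truth.

Everything the pipeline consumes can be generated here: a pixel grid with
woodland fractions and habitat composition, spatially autocorrelated
green-up truth, binomially cloud-thinned multispectral observations whose
noiseless EVI2 follows a double-logistic seasonal curve, nestboxes, breeding
records generated from a linear model with within-/between-year green-up
coupling modulated by local oak density, and an annual caterpillar half-fall
series.  All generators are pure functions of (config, seed), and every
observable traces back to a stored truth value (the ``TruthBundle``), so
downstream estimators can be tested against the quantities they estimate.

Spatial autocorrelation is produced by Gaussian-kernel smoothing of white
noise (bandwidth = ``spatial_range``), restandardized to unit variance —
simple and sufficient for sign- and recovery-level tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import CANOPY_SHARES, UNDERSTORY_SHARES, SimulationConfig
from .errors import InputError
from .evi2 import N_PERIODS, evi2_to_nir, period_midpoint
from .synchrony import habitat_overlay

_HABITAT_TAU = 1.0  # log-scale spatial heterogeneity of species shares
_CLOUD_RED = 0.42   # bright, flat reflectance written into cloudy looks
_CLOUD_NIR = 0.46


def _rng_of(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def smooth_field(rng: np.random.Generator, shape, range_m: float,
                 cell_size: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated Gaussian field on a grid."""
    z = rng.normal(size=shape)
    sigma = range_m / cell_size
    if sigma > 0:
        z = gaussian_filter(z, sigma=sigma, mode="nearest")
        sd = z.std()
        if sd > 0:
            z = (z - z.mean()) / sd
    return z


@dataclass
class Landscape:
    """Synthetic pixel grid, habitat composition and nestboxes."""

    grid: pd.DataFrame            # pixel_id, row, col, x, y, woodland_fraction
    habitat: pd.DataFrame         # per-pixel truth proportions (canopy_*/under_*)
    compartment_props: pd.DataFrame
    overlaps: pd.DataFrame        # compartment_id, pixel_id, area
    nestboxes: pd.DataFrame       # box_id, x, y, pixel_id, small_hole, covariates


def generate_landscape(config: SimulationConfig, rng=None) -> Landscape:
    """Grid, woodland fractions, habitat compartments and nestboxes.

    Woodland fraction is high in the interior and drops toward the grid
    border (the surrounding farmland).  Habitat composition lives on 120 m
    quadrant compartments (half a pixel) whose species shares follow
    spatially smoothed fields around the woodland-wide means; pixel-level
    truth is the area-weighted overlay of its four quadrants.  Nestboxes are
    placed uniformly within pixels that are more than half woodland.
    """
    rng = _rng_of(rng if rng is not None else config.seed)
    R, C, s = config.grid_rows, config.grid_cols, config.pixel_size

    rows, cols = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")
    ring = np.minimum.reduce([rows, cols, R - 1 - rows, C - 1 - cols])
    z = smooth_field(rng, (R, C), config.spatial_range, s)
    woodland = np.clip(0.88 - 0.65 * np.exp(-0.9 * ring) + 0.08 * z, 0.0, 1.0)

    grid = pd.DataFrame({
        "pixel_id": np.arange(R * C),
        "row": rows.ravel(), "col": cols.ravel(),
        "x": (cols.ravel() + 0.5) * s, "y": (rows.ravel() + 0.5) * s,
        "woodland_fraction": woodland.ravel(),
    })

    # habitat on the quadrant (half-pixel) compartment grid
    qR, qC = 2 * R, 2 * C
    qs = s / 2
    comp_ids = np.arange(qR * qC)
    comp_rows = {"compartment_id": comp_ids}
    for layer, shares, total in (("canopy", CANOPY_SHARES, 0.9),
                                 ("under", UNDERSTORY_SHARES, 0.9)):
        fields = {sp: smooth_field(rng, (qR, qC), config.spatial_range, qs)
                  for sp in shares}
        raw = {sp: shares[sp] * np.exp(_HABITAT_TAU * fields[sp]) for sp in shares}
        denom = sum(raw.values())
        for sp in shares:
            comp_rows[f"{layer}_{sp}"] = (total * raw[sp] / denom).ravel()
    compartment_props = pd.DataFrame(comp_rows)

    qrow, qcol = comp_ids // qC, comp_ids % qC
    overlaps = pd.DataFrame({
        "compartment_id": comp_ids,
        "pixel_id": (qrow // 2) * C + (qcol // 2),
        "area": np.full(comp_ids.size, qs * qs),
    })
    habitat = habitat_overlay(overlaps, compartment_props)

    # nestboxes in woodland pixels
    wood_mask = grid["woodland_fraction"].to_numpy() > 0.5
    wood_pixels = grid.loc[wood_mask, ["pixel_id", "row", "col"]].to_numpy()
    if not len(wood_pixels):
        raise InputError("no woodland pixels (>0.5) to place nestboxes in")
    pick = rng.integers(0, len(wood_pixels), size=config.n_nestboxes)
    prow, pcol = wood_pixels[pick, 1], wood_pixels[pick, 2]
    bx = (pcol + rng.uniform(0, 1, config.n_nestboxes)) * s
    by = (prow + rng.uniform(0, 1, config.n_nestboxes)) * s
    pixel_id = wood_pixels[pick, 0]

    alt_field = smooth_field(rng, (R, C), 3 * config.spatial_range, s)
    altitude = 110 + 25 * alt_field[prow, pcol] + rng.normal(0, 3, config.n_nestboxes)

    nonwood = grid.loc[~wood_mask, ["x", "y"]].to_numpy()
    if len(nonwood):
        d2 = ((bx[:, None] - nonwood[None, :, 0]) ** 2
              + (by[:, None] - nonwood[None, :, 1]) ** 2)
        edge = np.sqrt(d2.min(axis=1))
    else:
        ext_x, ext_y = C * s, R * s
        edge = np.minimum.reduce([bx, by, ext_x - bx, ext_y - by])

    oak_prop = habitat.set_index("pixel_id")["canopy_oak"].reindex(pixel_id).to_numpy()
    oak_density = rng.poisson(config.oak_density_scale * oak_prop)

    nestboxes = pd.DataFrame({
        "box_id": [f"B{i:04d}" for i in range(config.n_nestboxes)],
        "x": bx, "y": by, "pixel_id": pixel_id,
        "small_hole": rng.random(config.n_nestboxes) < 0.15,
        "altitude": altitude, "edge_distance": edge,
        "oak_density_75m": oak_density,
    })
    return Landscape(grid=grid, habitat=habitat, compartment_props=compartment_props,
                     overlaps=overlaps, nestboxes=nestboxes)


@dataclass
class TrueGreenup:
    """Ground-truth green-up dates: year effects plus a static spatial field
    plus independent pixel-year deviations."""

    years: np.ndarray        # calendar years
    year_means: np.ndarray   # annual site-level mean component
    dates: np.ndarray        # shape (n_years, n_pixels)

    def as_frame(self) -> pd.DataFrame:
        ny, npix = self.dates.shape
        return pd.DataFrame({
            "year": np.repeat(self.years, npix),
            "pixel_id": np.tile(np.arange(npix), ny),
            "true_greenup": self.dates.ravel(),
        })


def generate_true_greenup(config: SimulationConfig, rng=None) -> TrueGreenup:
    rng = _rng_of(rng if rng is not None else config.seed)
    R, C = config.grid_rows, config.grid_cols
    years = config.start_year + np.arange(config.n_years)
    year_means = rng.normal(config.mean_greenup, config.year_sd, config.n_years)
    spatial = config.spatial_sd * smooth_field(rng, (R, C), config.spatial_range,
                                               config.pixel_size).ravel()
    noise = rng.normal(0, config.greenup_noise_sd, (config.n_years, R * C))
    dates = year_means[:, None] + spatial[None, :] + noise
    return TrueGreenup(years=years, year_means=year_means, dates=dates)


def generate_cloud(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Per-year, per-8-day-period cloud fraction (%), seasonal + random."""
    rng = _rng_of(rng if rng is not None else config.seed)
    years = config.start_year + np.arange(config.n_years)
    periods = np.arange(1, N_PERIODS + 1)
    mid = np.array([period_midpoint(p) for p in periods])
    seasonal = (config.cloud_summer
                + (config.cloud_winter - config.cloud_summer)
                * 0.5 * (1 + np.cos(2 * np.pi * (mid - 15) / 365.25)))
    year_eff = rng.normal(0, config.cloud_year_sd, config.n_years)
    noise = rng.normal(0, config.cloud_period_sd, (config.n_years, N_PERIODS))
    frac = np.clip(seasonal[None, :] + year_eff[:, None] + noise, 0.0, 100.0)
    return pd.DataFrame({
        "year": np.repeat(years, N_PERIODS),
        "period": np.tile(periods, config.n_years),
        "cloud_fraction": frac.ravel(),
    })


def seasonal_evi2(day, greenup_day, config: SimulationConfig):
    """Noiseless double-logistic EVI2 curve: rise at green-up, fall at senescence."""
    day = np.asarray(day, dtype=float)
    r = config.logistic_rate
    rise = 1.0 / (1.0 + np.exp(-r * (day - np.asarray(greenup_day, dtype=float))))
    fall = 1.0 / (1.0 + np.exp(-r * (day - config.senescence_day)))
    return config.evi_base + config.evi_amplitude * (rise - fall)


def generate_observations(config: SimulationConfig, truth: TrueGreenup,
                          cloud: pd.DataFrame, rng=None,
                          include_cloudy: bool = True) -> pd.DataFrame:
    """Cloud-thinned multispectral looks for every pixel, period and year.

    Per pixel-period, ``n_clear ~ Binomial(looks_per_period, 1 - cloud/100)``.
    Clear looks carry a constant red reflectance and the NIR solved so that
    the look's EVI2 equals the seasonal curve at the period midpoint plus
    Gaussian index noise.  Cloudy looks (flagged 1) carry bright flat
    reflectance.  All looks in a period are dated at the period midpoint.
    """
    rng = _rng_of(rng if rng is not None else config.seed)
    cf = cloud.set_index(["year", "period"])["cloud_fraction"]
    if ((cf < 0) | (cf > 100)).any():
        raise InputError("cloud fractions must lie in [0, 100]")

    n_pix = config.n_pixels
    frames = []
    for yi, year in enumerate(truth.years):
        cfr = cf.loc[year].reindex(np.arange(1, N_PERIODS + 1)).to_numpy()
        if np.isnan(cfr).any():
            raise InputError(f"cloud series incomplete for year {year}")
        p_clear = 1.0 - cfr / 100.0
        n_clear = rng.binomial(config.looks_per_period, p_clear[None, :],
                               size=(n_pix, N_PERIODS))
        mids = period_midpoint(np.arange(1, N_PERIODS + 1))
        curve = seasonal_evi2(mids[None, :], truth.dates[yi][:, None], config)

        pix_idx = np.repeat(np.arange(n_pix), N_PERIODS)
        per_idx = np.tile(np.arange(N_PERIODS), n_pix)
        counts = n_clear.ravel()
        pix_clear = np.repeat(pix_idx, counts)
        per_clear = np.repeat(per_idx, counts)
        evi = (curve.ravel()[np.repeat(np.arange(n_pix * N_PERIODS), counts)]
               + rng.normal(0, config.obs_noise_sd, counts.sum()))
        red = np.full(evi.size, 0.05)
        nir = np.clip(evi2_to_nir(evi, red), 0.0, 1.0)
        clear_df = pd.DataFrame({
            "pixel_id": pix_clear, "doy": mids[per_clear],
            "red": red, "nir": nir, "cloudy": 0,
        })
        parts = [clear_df]
        if include_cloudy:
            n_cloudy = (config.looks_per_period - n_clear).ravel()
            pix_cl = np.repeat(pix_idx, n_cloudy)
            per_cl = np.repeat(per_idx, n_cloudy)
            parts.append(pd.DataFrame({
                "pixel_id": pix_cl, "doy": mids[per_cl],
                "red": _CLOUD_RED, "nir": _CLOUD_NIR, "cloudy": 1,
            }))
        ydf = pd.concat(parts, ignore_index=True)
        ydf["date"] = (pd.Timestamp(f"{year}-01-01")
                       + pd.to_timedelta(ydf.pop("doy") - 1, unit="D"))
        frames.append(ydf)
    out = pd.concat(frames, ignore_index=True)
    return out[["pixel_id", "date", "red", "nir", "cloudy"]]


def generate_breeding(config: SimulationConfig, landscape: Landscape,
                      truth: TrueGreenup, rng=None):
    """Breeding records and the caterpillar half-fall series.

    Laying (day-of-April) for a box b in year y:

        alpha + b_w * (g - gbar_y) * (1 + gain * oak_norm) + b_b * gbar_y
              + b_alt * altitude + b_edge * edge + b_oak * oak_density
              + yearRE + boxRE + eps

    with g the truth green-up of the box's pixel and gbar_y the annual mean
    over woodland pixels.  A small fraction of box-years add a late repeat
    clutch (~38 days after the year's first clutch) so the first-brood filter
    has something to remove.  Records are emitted as clutch observations
    (obs_day, eggs_observed) from which laying is recoverable exactly.
    """
    rng = _rng_of(rng if rng is not None else config.seed)
    grid = landscape.grid
    boxes = landscape.nestboxes
    wood = grid["woodland_fraction"].to_numpy() > 0.5
    gbar = truth.dates[:, wood].mean(axis=1)  # annual woodland mean green-up

    oak_norm = boxes["oak_density_75m"].to_numpy() / config.oak_density_scale
    covar_effect = (config.beta_altitude * boxes["altitude"].to_numpy()
                    + config.beta_edge * boxes["edge_distance"].to_numpy()
                    + config.beta_oak * boxes["oak_density_75m"].to_numpy())
    alpha = {
        "great_tit": (config.mean_laying - config.beta_between * config.mean_greenup
                      - covar_effect.mean()),
        "blue_tit": (config.mean_laying + config.blue_tit_offset
                     - config.beta_between * config.mean_greenup - covar_effect.mean()),
    }
    box_re = rng.normal(0, config.box_re_sd, len(boxes))
    pix_of_box = boxes["pixel_id"].to_numpy()

    records = []
    female_counter = 0
    for species in ("great_tit", "blue_tit"):
        eligible = (~boxes["small_hole"].to_numpy() if species == "great_tit"
                    else np.ones(len(boxes), dtype=bool))
        year_re = rng.normal(0, config.year_re_sd, config.n_years)
        current_female = np.full(len(boxes), -1, dtype=int)
        for yi, year in enumerate(truth.years):
            occupied = eligible & (rng.random(len(boxes)) < config.occupancy)
            idx = np.flatnonzero(occupied)
            if not idx.size:
                continue
            g = truth.dates[yi, pix_of_box[idx]]
            within = g - gbar[yi]
            lay = (alpha[species]
                   + config.beta_within * within
                   * (1 + config.oak_coupling_gain * oak_norm[idx])
                   + config.beta_between * gbar[yi]
                   + covar_effect[idx] + year_re[yi] + box_re[idx]
                   + rng.normal(0, config.residual_sd, idx.size))
            lay = np.round(lay).astype(int)
            clutch = np.maximum(3, np.round(rng.normal(config.mean_clutch, 1.2,
                                                       idx.size))).astype(int)
            eggs_obs = rng.integers(1, clutch + 1)
            hatch = (lay + clutch + config.incubation_days
                     + np.round(rng.normal(0, 1.0, idx.size)).astype(int))
            hatch = np.maximum(hatch, lay + 1)

            # female turnover: returners keep their id
            stay = rng.random(idx.size) < config.female_return_prob
            new = ~stay | (current_female[idx] < 0)
            n_new = int(new.sum())
            current_female[idx[new]] = female_counter + np.arange(n_new)
            female_counter += n_new
            fem = np.array([f"F{f:05d}" for f in current_female[idx]], dtype=object)
            fem[rng.random(idx.size) > config.female_known_prob] = None

            records.append(pd.DataFrame({
                "box_id": boxes["box_id"].to_numpy()[idx],
                "year": int(year), "species": species,
                "laying_day": lay, "obs_day": lay + eggs_obs - 1,
                "eggs_observed": eggs_obs, "hatch_day": hatch, "female_id": fem,
            }))
            # a few late repeat clutches, to be caught by the first-brood filter
            n_second = rng.binomial(idx.size, 0.02)
            if n_second:
                j = rng.choice(idx.size, n_second, replace=False)
                lay2 = lay.min() + 38 + rng.integers(0, 12, n_second)
                eggs2 = rng.integers(1, 6, n_second)
                records.append(pd.DataFrame({
                    "box_id": boxes["box_id"].to_numpy()[idx[j]],
                    "year": int(year), "species": species,
                    "laying_day": lay2, "obs_day": lay2 + eggs2 - 1,
                    "eggs_observed": eggs2,
                    "hatch_day": lay2 + 20, "female_id": fem[j],
                }))
    breeding = pd.concat(records, ignore_index=True)

    halffall = pd.DataFrame({
        "year": truth.years,
        "halffall_day": (config.halffall_mean
                         + config.halffall_slope * (gbar - config.mean_greenup)
                         + rng.normal(0, config.halffall_noise_sd, config.n_years)),
    })
    return breeding, halffall


@dataclass
class TruthBundle:
    """Everything the generator knows that an estimator could be tested against."""

    config: SimulationConfig
    landscape: Landscape
    greenup: TrueGreenup
    cloud: pd.DataFrame
    observations: pd.DataFrame
    breeding: pd.DataFrame
    halffall: pd.DataFrame

    @property
    def true_betas(self) -> dict:
        c = self.config
        return {"within": c.beta_within, "between": c.beta_between,
                "altitude": c.beta_altitude, "edge": c.beta_edge, "oak": c.beta_oak,
                "oak_coupling_gain": c.oak_coupling_gain}

    @property
    def annual_mean_greenup(self) -> pd.Series:
        wood = self.landscape.grid["woodland_fraction"].to_numpy() > 0.5
        return pd.Series(self.greenup.dates[:, wood].mean(axis=1),
                         index=self.greenup.years, name="true_mean_greenup")

    def truth_json(self) -> str:
        return json.dumps({
            "config": self.config.to_dict(),
            "true_betas": self.true_betas,
            "year_means": dict(zip(map(int, self.greenup.years),
                                   map(float, self.greenup.year_means))),
            "annual_mean_greenup": {int(k): float(v)
                                    for k, v in self.annual_mean_greenup.items()},
        }, indent=2)


def simulate_dataset(config: SimulationConfig, include_cloudy: bool = True,
                     skip_observations: bool = False) -> TruthBundle:
    """Run every generator with independent streams derived from config.seed."""
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in streams]
    landscape = generate_landscape(config, rngs[0])
    truth = generate_true_greenup(config, rngs[1])
    cloud = generate_cloud(config, rngs[2])
    if skip_observations:
        obs = pd.DataFrame(columns=["pixel_id", "date", "red", "nir", "cloudy"])
    else:
        obs = generate_observations(config, truth, cloud, rngs[3],
                                    include_cloudy=include_cloudy)
    breeding, halffall = generate_breeding(config, landscape, truth, rngs[4])
    return TruthBundle(config=config, landscape=landscape, greenup=truth,
                       cloud=cloud, observations=obs, breeding=breeding,
                       halffall=halffall)


def write_dataset(bundle: TruthBundle, outdir) -> dict:
    """Write the CSV inputs the pipeline reads, plus truth.json. Returns paths."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name, df):
        p = out / name
        df.to_csv(p, index=False)
        paths[name] = p

    _write("grid.csv", bundle.landscape.grid)
    _write("habitat_truth.csv", bundle.landscape.habitat)
    _write("compartments.csv", bundle.landscape.compartment_props)
    _write("overlaps.csv", bundle.landscape.overlaps)
    _write("nestboxes.csv", bundle.landscape.nestboxes)
    _write("observations.csv", bundle.observations)
    _write("cloud.csv", bundle.cloud)
    # laying is withheld: the pipeline must infer it from the clutch observation
    _write("breeding.csv", bundle.breeding.drop(columns=["laying_day"]))
    _write("halffall.csv", bundle.halffall)
    _write("true_greenup.csv", bundle.greenup.as_frame())
    (out / "truth.json").write_text(bundle.truth_json())
    paths["truth.json"] = out / "truth.json"
    return paths
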