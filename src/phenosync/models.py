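"""Annual correlations and individual-level mixed models.

The central statistical device is within/between-year centering of the
green-up predictor: each record's nestbox green-up g is split into the
annual mean (between-year component) and the deviation from it (within-year
component), so the mixed model separates "birds lay later in late springs"
from "birds in locally late spots lay later than their neighbours the same
year".  The decomposition is exact: between + within = g for every record.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, UndefinedStatisticError
from .mixedlm import MixedLMResult, fit_mixed_lm

FULL_COVARIATES = ("altitude", "edge_distance", "oak_density_75m")


def annual_correlation(x, y):
    """Pearson r between two yearly series on complete pairs.

    Returns ``(r, p, n)``; requires >= 3 complete pairs and nonzero variance
    in both series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("series length mismatch")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise UndefinedStatisticError(f"need >= 3 complete year pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero variance in a series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(n)


def partition_within_between(table: pd.DataFrame, value_col: str = "greenup",
                             year_col: str = "year") -> pd.DataFrame:
    """Split a predictor into annual means and within-year deviations.

    Adds ``<value>_between`` (the mean of the predictor over records of the
    year) and ``<value>_within`` (the record's deviation from it);
    between + within reconstructs the value exactly.
    """
    out = table.copy()
    between = out.groupby(year_col)[value_col].transform("mean")
    out[value_col + "_between"] = between
    out[value_col + "_within"] = out[value_col] - between
    return out


def annual_mean_greenup(greenup_map: pd.DataFrame, grid_df: pd.DataFrame,
                        year=None, woodland_threshold: float = 0.5):
    """Unweighted mean green-up over pixels with woodland fraction strictly
    above the threshold and a valid (converged) estimate.

    With ``year=None`` returns a Series over all years; otherwise a scalar.
    """
    wood = grid_df.loc[grid_df["woodland_fraction"] > woodland_threshold, "pixel_id"]
    sub = greenup_map[greenup_map["pixel_id"].isin(wood) & greenup_map["converged"]
                      & greenup_map["greenup_day"].notna()]
    if year is not None:
        sub = sub[sub["year"] == year]
        if not len(sub):
            raise UndefinedStatisticError(f"no qualifying pixels in year {year}")
        return float(sub["greenup_day"].mean())
    if not len(sub):
        raise UndefinedStatisticError("no qualifying pixels in any year")
    return sub.groupby("year")["greenup_day"].mean()


def fit_breeding_lmm(table: pd.DataFrame, response: str = "laying_day",
                     covariates: str = "full", female_re: bool = False,
                     greenup_col: str = "greenup",
                     theta0=None, fixed_theta: bool = False) -> MixedLMResult:
    """Mixed model of a breeding date on partitioned green-up.

    Fixed effects: intercept, green-up (within-year), green-up (between-year)
    and, for ``covariates="full"``, altitude, woodland-edge distance and
    local oak density.  Random intercepts: year and nestbox, plus female
    identity when ``female_re`` (rows with unknown female are then dropped,
    as they must be).
    """
    if covariates not in ("minimal", "full"):
        raise InputError("covariates must be 'minimal' or 'full'")
    df = table.copy()
    if female_re:
        df = df[df["female_id"].notna()]
    df = df[df[response].notna() & df[greenup_col].notna()]
    if df.empty:
        raise InputError("no usable rows for the mixed model")
    df = partition_within_between(df, value_col=greenup_col)

    fixed = ["greenup_within", "greenup_between"]
    X = pd.DataFrame({
        "intercept": np.ones(len(df)),
        "greenup_within": df[greenup_col + "_within"].to_numpy(),
        "greenup_between": df[greenup_col + "_between"].to_numpy(),
    })
    if covariates == "full":
        for c in FULL_COVARIATES:
            X[c] = df[c].to_numpy(dtype=float)
    random = {"year": df["year"].to_numpy(), "nestbox": df["box_id"].to_numpy()}
    if female_re:
        random["female"] = df["female_id"].to_numpy()
    return fit_mixed_lm(df[response].to_numpy(dtype=float), X, random,
                        theta0=theta0, fixed_theta=fixed_theta)


def phenology_residuals(table: pd.DataFrame, response: str = "laying_day",
                        female_re: bool = False) -> pd.Series:
    """Breeding dates corrected for annual (and optionally female) effects.

    Residuals from an intercept-only mixed model with year (+ female) random
    intercepts; used as the value vector for spatial correlograms.
    """
    df = table[table[response].notna()].copy()
    if female_re:
        df = df[df["female_id"].notna()]
    X = np.ones((len(df), 1))
    random = {"year": df["year"].to_numpy()}
    if female_re:
        random["female"] = df["female_id"].to_numpy()
    fit = fit_mixed_lm(df[response].to_numpy(dtype=float), X, random,
                       names=["intercept"])
    return pd.Series(fit.resid, index=df.index)


def annual_phenology_table(greenup_map: pd.DataFrame, grid_df: pd.DataFrame,
                           table: pd.DataFrame, halffall: pd.DataFrame | None = None,
                           woodland_threshold: float = 0.5) -> pd.DataFrame:
    """Per-year summary: woodland mean green-up, species mean laying/hatch
    dates with standard errors, and caterpillar half-fall date."""
    mean_g = annual_mean_greenup(greenup_map, grid_df,
                                 woodland_threshold=woodland_threshold)
    out = mean_g.rename("mean_greenup").reset_index()
    for sp, grp in table.groupby("species"):
        agg = grp.groupby("year").agg(
            mean_laying=("laying_day", "mean"),
            se_laying=("laying_day", "sem"),
            n_attempts=("laying_day", "size"))
        if "hatch_day" in grp.columns:
            agg["mean_hatch"] = grp.groupby("year")["hatch_day"].mean()
        agg.columns = [f"{c}_{sp}" for c in agg.columns]
        out = out.merge(agg.reset_index(), on="year", how="left")
    if halffall is not None:
        out = out.merge(halffall[["year", "halffall_day"]], on="year", how="left")
    return out
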