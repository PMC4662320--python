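"""Pixel-level phenological synchrony and its habitat drivers.

Synchrony at a pixel is the across-year Pearson correlation between the mean
laying date of breeding attempts in that pixel and the pixel's green-up
date.  Pixels are mapped by the nestbox's containing pixel.  Habitat
regressions relate the per-pixel correlation to canopy/understory
composition, one species proportion at a time (the proportions are
compositional, hence not independent), weighted by the number of breeding
attempts behind each correlation.
"""

from __future__ import annotations

import json
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InputError, UndefinedStatisticError

DEFAULT_MIN_YEARS = 6


def pixel_synchrony(table: pd.DataFrame, greenup_map: pd.DataFrame,
                    grid_df: pd.DataFrame, min_years: int = DEFAULT_MIN_YEARS,
                    woodland_threshold: float = 0.5) -> pd.DataFrame:
    """Across-year laying/green-up correlation per pixel.

    Parameters
    ----------
    table : analysis table with ``pixel_id``, ``year``, ``laying_day``
        (already restricted to one species).
    greenup_map : per pixel-year green-up dates (``converged`` flag respected).
    grid_df : pixel table with ``pixel_id`` and ``woodland_fraction``.

    Returns
    -------
    One row per woodland pixel: ``r``, ``n_years``, ``n_attempts``,
    ``included`` and an ``exclude_reason`` ("" when included).  ``r`` is NaN
    when undefined (fewer than 3 year-points or zero variance).
    """
    if "pixel_id" not in table.columns:
        raise InputError("analysis table needs a pixel_id column")
    wood = grid_df[grid_df["woodland_fraction"] > woodland_threshold]["pixel_id"]
    yearly = (table.groupby(["pixel_id", "year"])["laying_day"]
              .agg(mean_laying="mean", n="size").reset_index())
    g = greenup_map[greenup_map["converged"]][["pixel_id", "year", "greenup_day"]]
    yearly = yearly.merge(g, on=["pixel_id", "year"], how="inner")

    rows = []
    for pixel_id in wood:
        sub = yearly[yearly["pixel_id"] == pixel_id]
        n_years = len(sub)
        n_attempts = int(sub["n"].sum())
        r = np.nan
        reason = ""
        if n_years < 3:
            reason = "too_few_years"
        elif sub["mean_laying"].std() == 0 or sub["greenup_day"].std() == 0:
            reason = "zero_variance"
        else:
            r = float(stats.pearsonr(sub["mean_laying"], sub["greenup_day"])[0])
            if n_years < min_years:
                reason = "below_min_years"
        rows.append({"pixel_id": pixel_id, "r": r, "n_years": n_years,
                     "n_attempts": n_attempts, "included": reason == "",
                     "exclude_reason": reason})
    return pd.DataFrame(rows)


def habitat_overlay(overlaps: pd.DataFrame, compartment_props: pd.DataFrame) -> pd.DataFrame:
    """Area-weighted habitat composition per pixel.

    Parameters
    ----------
    overlaps : rows (compartment_id, pixel_id, area) giving the intersection
        area of each habitat compartment with each pixel.
    compartment_props : per-compartment species proportions (columns besides
        ``compartment_id`` are carried through).

    Pixel values are sums of compartment proportions weighted by area shares
    renormalized over the pixel's covered area; a pixel with zero covered
    area is absent from the output.
    """
    need = {"compartment_id", "pixel_id", "area"}
    if not need <= set(overlaps.columns):
        raise InputError(f"overlaps table needs columns {sorted(need)}")
    df = overlaps.merge(compartment_props, on="compartment_id", how="left")
    prop_cols = [c for c in compartment_props.columns if c != "compartment_id"]
    total = df.groupby("pixel_id")["area"].transform("sum")
    df = df[total > 0].copy()
    share = df["area"] / df.groupby("pixel_id")["area"].transform("sum")
    for c in prop_cols:
        df[c] = df[c] * share
    return df.groupby("pixel_id")[prop_cols].sum().reset_index()


def synchrony_habitat_regression(sync: pd.DataFrame, habitat: pd.DataFrame,
                                 habitat_var: str, weight_col: str = "n_attempts",
                                 restrict_to_included: bool = False) -> dict:
    """Weighted least squares of pixel synchrony on one habitat proportion.

    By default every woodland pixel with a defined correlation enters
    (weights handle the varying support); ``restrict_to_included`` instead
    keeps only pixels passing the min-years rule.
    """
    df = sync.merge(habitat[["pixel_id", habitat_var]], on="pixel_id", how="inner")
    df = df[df["r"].notna() & df[habitat_var].notna()]
    if restrict_to_included:
        df = df[df["included"]]
    if len(df) < 3:
        raise UndefinedStatisticError("need >= 3 pixels for the habitat regression")
    x = df[habitat_var].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise UndefinedStatisticError(f"habitat variable {habitat_var!r} is constant")
    w = df[weight_col].to_numpy(dtype=float)
    X = sm.add_constant(x)
    fit = sm.WLS(df["r"].to_numpy(dtype=float), X, weights=w).fit()
    return {"habitat_var": habitat_var, "slope": float(fit.params[1]),
            "se": float(fit.bse[1]), "t": float(fit.tvalues[1]),
            "p": float(fit.pvalues[1]), "intercept": float(fit.params[0]),
            "n_pixels": int(len(df))}


def habitat_regression_table(sync: pd.DataFrame, habitat: pd.DataFrame,
                             habitat_vars=None, species: str | None = None,
                             **kwargs) -> pd.DataFrame:
    """One synchrony~habitat regression per habitat variable."""
    if habitat_vars is None:
        habitat_vars = [c for c in habitat.columns if c != "pixel_id"]
    rows = []
    for var in habitat_vars:
        try:
            res = synchrony_habitat_regression(sync, habitat, var, **kwargs)
        except UndefinedStatisticError:
            continue
        if species is not None:
            res["species"] = species
        rows.append(res)
    return pd.DataFrame(rows)


def compare_species_synchrony(sync_a: pd.DataFrame, sync_b: pd.DataFrame) -> dict:
    """Welch two-sample t-test on included pixel correlations of two species,
    plus the paired correlation over pixels common to both maps."""
    a = sync_a.loc[sync_a["included"], ["pixel_id", "r"]].dropna()
    b = sync_b.loc[sync_b["included"], ["pixel_id", "r"]].dropna()
    if len(a) < 2 or len(b) < 2:
        raise InputError("each map needs >= 2 included pixels")
    out = {
        "mean_a": float(a["r"].mean()), "se_a": float(a["r"].sem()), "n_a": int(len(a)),
        "mean_b": float(b["r"].mean()), "se_b": float(b["r"].sem()), "n_b": int(len(b)),
    }
    if a["r"].std() == 0 and b["r"].std() == 0:
        out.update(t=np.inf if out["mean_a"] != out["mean_b"] else 0.0,
                   df=np.nan, p=np.nan, degenerate=True)
        return out
    t, p = stats.ttest_ind(a["r"], b["r"], equal_var=False)
    va, vb = a["r"].var() / len(a), b["r"].var() / len(b)
    df_w = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    out.update(t=float(t), df=float(df_w), p=float(p), degenerate=False)
    common = a.merge(b, on="pixel_id", suffixes=("_a", "_b"))
    if len(common) >= 3 and common["r_a"].std() > 0 and common["r_b"].std() > 0:
        r, pr = stats.pearsonr(common["r_a"], common["r_b"])
        out.update(paired_r=float(r), paired_p=float(pr), n_common=int(len(common)))
    return out


def save_species_comparison(result: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(result, fh, indent=2)
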