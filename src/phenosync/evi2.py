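"""Two-band enhanced vegetation index (EVI2) series from cloud-flagged observations.

EVI2 = 2.5 * (NIR - Red) / (NIR + 2.4 * Red + 1)

Each calendar year is divided into 46 8-day periods anchored at 1 January
(the last period is 5-6 days long).  The per-pixel, per-period index value is
the arithmetic mean of EVI2 over the cloud-free looks in that period; periods
with no clear look are missing.  "Middle day" of a period covering days
d .. d+7 is fixed as d+3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError

N_PERIODS = 46
#: valid EVI2 range for reflectances in [0, 1]
EVI2_MIN, EVI2_MAX = -0.7353, 1.25


def compute_evi2(red, nir):
    """EVI2 from red and near-infrared reflectance (both in [0, 1]).

    Accepts scalars or arrays; monotonically increasing in NIR at fixed red.
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if np.any((red < 0) | (red > 1)) or np.any((nir < 0) | (nir > 1)):
        raise InputError("reflectances must lie in [0, 1]")
    out = 2.5 * (nir - red) / (nir + 2.4 * red + 1.0)
    return out if out.ndim else float(out)


def evi2_to_nir(evi2, red):
    """Invert the index for NIR at fixed red: the synthetic generator's mapping.

    EVI2 is monotone in NIR, so for v < 2.5 the solution is unique:
    NIR = (2.5*Red + v*(2.4*Red + 1)) / (2.5 - v).
    """
    evi2 = np.asarray(evi2, dtype=float)
    red = np.asarray(red, dtype=float)
    out = (2.5 * red + evi2 * (2.4 * red + 1.0)) / (2.5 - evi2)
    return out if out.ndim else float(out)


def period_of_day(day_of_year):
    """8-day period index (1..46) containing a day of year; days 361+ fall in period 46."""
    day = np.asarray(day_of_year)
    if np.any((day < 1) | (day > 366)):
        raise InputError("day of year must lie in 1..366")
    p = np.minimum((day - 1) // 8 + 1, N_PERIODS)
    return p if p.ndim else int(p)


def period_midpoint(period_index):
    """Middle day (day-of-year) of an 8-day period: 8*(k-1) + 4."""
    idx = np.asarray(period_index)
    if np.any((idx < 1) | (idx > N_PERIODS)):
        raise InputError(f"period index must lie in 1..{N_PERIODS}")
    mid = 8 * (idx - 1) + 4
    return mid if mid.ndim else int(mid)


def aggregate_periods(observations: pd.DataFrame) -> pd.DataFrame:
    """Collapse cloud-flagged observations into per-pixel-year 8-day EVI2 series.

    Parameters
    ----------
    observations : DataFrame with columns ``pixel_id``, ``date`` (parseable to
        datetime), ``red``, ``nir``, ``cloudy`` (0/1).

    Returns
    -------
    DataFrame with one row per (pixel_id, year, period): columns ``pixel_id``,
    ``year``, ``period``, ``midpoint_day``, ``evi2`` (NaN when no clear look)
    and ``n_clear``.  Every period 1..46 is present for every pixel-year that
    appears in the input, so missing periods are explicit.
    """
    cols = {"pixel_id", "date", "red", "nir", "cloudy"}
    missing = cols - set(observations.columns)
    if missing:
        raise InputError(f"observations table lacks columns: {sorted(missing)}")

    obs = observations.copy()
    dates = pd.to_datetime(obs["date"])
    obs["year"] = dates.dt.year.to_numpy()
    obs["period"] = np.minimum((dates.dt.dayofyear.to_numpy() - 1) // 8 + 1, N_PERIODS)

    clear = obs.loc[obs["cloudy"].astype(int) == 0].copy()
    if len(clear):
        clear["evi2"] = compute_evi2(clear["red"].to_numpy(), clear["nir"].to_numpy())
        agg = (clear.groupby(["pixel_id", "year", "period"])["evi2"]
               .agg(evi2="mean", n_clear="size").reset_index())
    else:
        agg = pd.DataFrame(columns=["pixel_id", "year", "period", "evi2", "n_clear"])

    universe = obs[["pixel_id", "year"]].drop_duplicates()
    full = universe.merge(pd.DataFrame({"period": np.arange(1, N_PERIODS + 1)}), how="cross")
    out = full.merge(agg, on=["pixel_id", "year", "period"], how="left")
    out["evi2"] = pd.to_numeric(out["evi2"], errors="coerce")
    out["n_clear"] = pd.to_numeric(out["n_clear"], errors="coerce").fillna(0).astype(int)
    out["midpoint_day"] = 8 * (out["period"] - 1) + 4
    return out[["pixel_id", "year", "period", "midpoint_day", "evi2", "n_clear"]].sort_values(
        ["pixel_id", "year", "period"], ignore_index=True)
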