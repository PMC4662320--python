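"""Sliding-window scan of annual synchrony against early-spring cloudiness.

Cloud obscures the ground, thins the clear-look count behind each 8-day EVI2
value, and so degrades the green-up estimates; the scan asks over which
early-year window mean cloudiness best predicts how well birds and
vegetation phenology correlate each year.  With the default bounds (window
lengths 3..15 periods within the first 15 periods = 120 days) there are 91
candidate windows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, UndefinedStatisticError

DEFAULT_MIN_LEN = 3
DEFAULT_MAX_LEN = 15
DEFAULT_HORIZON = 15


def enumerate_windows(min_len: int = DEFAULT_MIN_LEN, max_len: int = DEFAULT_MAX_LEN,
                      horizon: int = DEFAULT_HORIZON):
    """All contiguous (start_period, length) windows within the horizon.

    Periods are 1-based; a window (s, L) covers periods s .. s+L-1.  Default
    bounds give 91 windows.
    """
    if not (1 <= min_len <= max_len <= horizon):
        if min_len > horizon:
            warnings.warn("min_len exceeds horizon; no windows", stacklevel=2)
            return []
        raise ConfigError("require 1 <= min_len <= max_len <= horizon")
    return [(s, L) for L in range(min_len, max_len + 1)
            for s in range(1, horizon - L + 2)]


def annual_synchrony_series(table: pd.DataFrame, laying_col: str = "laying_day",
                            greenup_col: str = "greenup",
                            min_pairs: int = 3) -> pd.Series:
    """Per-year Pearson r between individual laying dates and nestbox green-up.

    Years with fewer than ``min_pairs`` complete records, or zero variance,
    are NaN.
    """
    out = {}
    for year, grp in table.groupby("year"):
        sub = grp[[laying_col, greenup_col]].dropna()
        if (len(sub) < min_pairs or sub[laying_col].std() == 0
                or sub[greenup_col].std() == 0):
            out[int(year)] = np.nan
            continue
        out[int(year)] = float(stats.pearsonr(sub[laying_col], sub[greenup_col])[0])
    return pd.Series(out, name="synchrony").rename_axis("year").sort_index()


def window_mean_cloud(cloud: pd.DataFrame, window) -> pd.Series:
    """Per-year unweighted mean cloud fraction over the window's periods."""
    s, L = window
    sub = cloud[(cloud["period"] >= s) & (cloud["period"] <= s + L - 1)]
    counts = sub.groupby("year")["cloud_fraction"].size()
    if (counts != L).any():
        raise UndefinedStatisticError(
            f"cloud series incomplete for window {window} in some years")
    return sub.groupby("year")["cloud_fraction"].mean()


def scan_windows(windows, cloud: pd.DataFrame, synchrony: pd.Series) -> pd.DataFrame:
    """Regress annual synchrony on each window's mean cloudiness and rank.

    Returns one row per window: slope, intercept, SE, t, p, r; rank_abs
    (1 = largest |r|, ties broken by (start, length)) and rank_signed
    (descending r).  Windows whose cloudiness is constant across the usable
    years are excluded from ranking and flagged.
    """
    sync = synchrony.dropna()
    rows = []
    for (s, L) in windows:
        mc = window_mean_cloud(cloud, (s, L))
        joined = pd.concat([mc.rename("cloud"), sync.rename("sync")], axis=1).dropna()
        rec = {"start": s, "length": L, "n_years": len(joined)}
        if len(joined) < 3:
            raise UndefinedStatisticError("need >= 3 overlapping years")
        if joined["cloud"].std() == 0:
            rec.update(slope=np.nan, intercept=np.nan, se=np.nan, t=np.nan,
                       p=np.nan, r=np.nan, excluded=True)
        else:
            fit = stats.linregress(joined["cloud"], joined["sync"])
            rec.update(slope=fit.slope, intercept=fit.intercept, se=fit.stderr,
                       t=fit.slope / fit.stderr if fit.stderr > 0 else np.inf,
                       p=fit.pvalue, r=fit.rvalue, excluded=False)
        rows.append(rec)
    out = pd.DataFrame(rows)

    ranked = out[~out["excluded"]].sort_values(
        by=["r", "start", "length"],
        key=lambda s: -s.abs() if s.name == "r" else s)
    out["rank_abs"] = np.nan
    out.loc[ranked.index, "rank_abs"] = np.arange(1, len(ranked) + 1)
    signed = out[~out["excluded"]].sort_values(
        by=["r", "start", "length"], ascending=[False, True, True])
    out["rank_signed"] = np.nan
    out.loc[signed.index, "rank_signed"] = np.arange(1, len(signed) + 1)
    return out


def top_windows(scan: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """The k windows with the largest |r|."""
    return scan[~scan["excluded"]].nsmallest(k, "rank_abs")
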