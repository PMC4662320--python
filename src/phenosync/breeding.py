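"""Breeding-record preparation: laying-date inference, first-brood filtering,
covariate joins.

Tits lay one egg per day, so the first-egg ("laying") date of an incomplete
clutch observed with k eggs on day d is d - (k - 1).  Laying and hatch dates
are kept on the day-of-April scale (1 = 1 April; March dates are <= 0), the
scale on which mean tit laying dates are conventionally reported; green-up
dates stay on day-of-year.
"""

from __future__ import annotations

import calendar
import datetime as dt
import logging

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_BROOD_WINDOW = 30


def april_day_to_doy(april_day, year):
    """Day-of-April -> day-of-year (31 March is day 90, or 91 in leap years)."""
    offset = 90 + int(calendar.isleap(int(year)))
    return np.asarray(april_day) + offset if np.ndim(april_day) else april_day + offset


def doy_to_april_day(doy, year):
    """Day-of-year -> day-of-April."""
    offset = 90 + int(calendar.isleap(int(year)))
    return np.asarray(doy) - offset if np.ndim(doy) else doy - offset


def infer_laying_date(observation_date, eggs_observed):
    """Back-count one egg per day: laying = observation date - (eggs - 1).

    ``observation_date`` may be a date(time) or an integer day on any linear
    day scale; the result is on the same scale (3 eggs on 3 April -> 1 April).
    """
    eggs = np.asarray(eggs_observed)
    if np.any(eggs < 1):
        raise InputError("eggs_observed must be >= 1")
    back = eggs - 1
    if isinstance(observation_date, (dt.date, dt.datetime, pd.Timestamp)):
        return observation_date - dt.timedelta(days=int(back))
    obs = np.asarray(observation_date)
    out = obs - back
    return out if out.ndim else out.item()


def filter_first_broods(records: pd.DataFrame, window: int = DEFAULT_BROOD_WINDOW,
                        laying_col: str = "laying_day",
                        by=("year", "species")):
    """Keep clutches laid within ``window`` days (inclusive) of the year's first clutch.

    The reference first clutch is taken per year and species, since the two
    species are analyzed separately.  Returns ``(kept, excluded)`` frames;
    the earliest clutch of a group is always kept.
    """
    by = [c for c in by if c in records.columns]
    if not len(records):
        return records.copy(), records.copy()
    first = records.groupby(by)[laying_col].transform("min")
    keep = records[laying_col] <= first + window
    kept, excluded = records[keep].copy(), records[~keep].copy()
    if len(excluded):
        logger.info("first-brood filter: kept %d, excluded %d records",
                    len(kept), len(excluded))
    return kept, excluded


def join_covariates(records: pd.DataFrame, nestboxes: pd.DataFrame,
                    nestbox_greenup: pd.DataFrame):
    """Assemble the analysis table: one row per breeding attempt with its
    nestbox green-up and habitat covariates.

    Returns ``(table, rejects)``.  Rejects are records whose box is unknown or
    whose box-year has no assignable green-up; they are reported, not silently
    dropped (retained + rejected = input size).
    """
    box_cols = ["box_id", "x", "y", "altitude", "edge_distance", "oak_density_75m"]
    if "pixel_id" in nestboxes.columns:
        box_cols.append("pixel_id")
    merged = records.merge(nestboxes[box_cols], on="box_id", how="left", indicator=True)
    unknown_box = merged["_merge"] == "left_only"
    merged = merged.drop(columns="_merge")

    merged = merged.merge(
        nestbox_greenup[["box_id", "year", "greenup_day"]].rename(
            columns={"greenup_day": "greenup"}),
        on=["box_id", "year"], how="left")
    no_greenup = merged["greenup"].isna() & ~unknown_box

    reject_mask = unknown_box | no_greenup
    rejects = merged[reject_mask].copy()
    rejects["reject_reason"] = np.where(unknown_box[reject_mask], "unknown_box",
                                        "no_nestbox_greenup")
    table = merged[~reject_mask].reset_index(drop=True)
    if len(rejects):
        logger.info("covariate join: %d records kept, %d rejected (%d unknown box, "
                    "%d without nestbox green-up)", len(table), len(rejects),
                    int(unknown_box.sum()), int(no_greenup.sum()))
    return table, rejects.reset_index(drop=True)


def prepare_analysis_table(records: pd.DataFrame, nestboxes: pd.DataFrame,
                           nestbox_greenup: pd.DataFrame,
                           brood_window: int = DEFAULT_BROOD_WINDOW):
    """Full preparation: infer laying where needed, filter first broods, join.

    ``records`` needs either a ``laying_day`` column or ``obs_day`` +
    ``eggs_observed`` (day-of-April integers).  Returns
    ``(table, excluded, rejects)``.
    """
    rec = records.copy()
    if "laying_day" not in rec.columns or rec["laying_day"].isna().any():
        if not {"obs_day", "eggs_observed"} <= set(rec.columns):
            raise InputError("records need laying_day or obs_day + eggs_observed")
        inferred = infer_laying_date(rec["obs_day"].to_numpy(),
                                     rec["eggs_observed"].to_numpy())
        if "laying_day" in rec.columns:
            rec["laying_day"] = rec["laying_day"].fillna(pd.Series(inferred, index=rec.index))
        else:
            rec["laying_day"] = inferred
    kept, excluded = filter_first_broods(rec, window=brood_window)
    table, rejects = join_covariates(kept, nestboxes, nestbox_greenup)
    return table, excluded, rejects
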