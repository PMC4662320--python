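"""Nestbox-level green-up from the pixel map.

A nestbox inherits a weighted mean of the green-up dates of its four nearest
pixel centers.  Weights are the bilinear interpolation weights for the box
position, multiplied by each pixel's woodland fraction (so non-woodland
pixels contribute nothing), then renormalized over pixels with a valid
green-up estimate.  This is the simplest scheme consistent with weighting a
box "by where in the pixel it sits and by how much of the pixel is
woodland"; the exact procedure used with the original ArcGIS data is not
reproducible from its description, so this interpretation is documented
rather than asserted (see docs/methods.md).

Boxes whose four-neighbourhood carries zero weight fall back to the nearest
valid woodland pixel within ``fallback_radius`` (default 360 m, 1.5 pixels);
beyond that they are not assignable and are dropped with a log entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, NotAssignableError

logger = logging.getLogger(__name__)

DEFAULT_FALLBACK_RADIUS = 360.0


@dataclass
class PixelGrid:
    """Regular pixel grid, row-major from the north-west corner.

    ``x`` grows east, ``y`` grows south; pixel (r, c) covers the half-open
    square [c*s, (c+1)*s) x [r*s, (r+1)*s) with s = ``pixel_size``.
    """

    n_rows: int
    n_cols: int
    pixel_size: float
    woodland_fraction: np.ndarray  # shape (n_rows, n_cols)

    def __post_init__(self):
        self.woodland_fraction = np.asarray(self.woodland_fraction, dtype=float)
        if self.woodland_fraction.shape != (self.n_rows, self.n_cols):
            raise InputError("woodland_fraction shape does not match grid dims")
        if np.any((self.woodland_fraction < 0) | (self.woodland_fraction > 1)):
            raise InputError("woodland fractions must lie in [0, 1]")

    @classmethod
    def from_dataframe(cls, grid_df: pd.DataFrame, pixel_size: float | None = None):
        """Build from a table with columns row, col, woodland_fraction (+ x, y)."""
        n_rows = int(grid_df["row"].max()) + 1
        n_cols = int(grid_df["col"].max()) + 1
        if pixel_size is None:
            xs = np.sort(grid_df.loc[grid_df["row"] == 0, "x"].unique())
            pixel_size = float(np.diff(xs).min()) if xs.size > 1 else float(2 * xs[0])
        wf = np.full((n_rows, n_cols), np.nan)
        wf[grid_df["row"].to_numpy(), grid_df["col"].to_numpy()] = \
            grid_df["woodland_fraction"].to_numpy(dtype=float)
        return cls(n_rows, n_cols, pixel_size, wf)

    @property
    def extent(self):
        return self.n_cols * self.pixel_size, self.n_rows * self.pixel_size

    def pixel_id(self, row, col):
        return row * self.n_cols + col

    def pixel_of_point(self, x, y):
        """Pixel id containing a point (half-open membership)."""
        col = int(np.floor(x / self.pixel_size))
        row = int(np.floor(y / self.pixel_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise InputError(f"point ({x}, {y}) outside grid extent")
        return self.pixel_id(row, col)

    def centers(self):
        """(x, y) center coordinates, each shape (n_rows, n_cols)."""
        s = self.pixel_size
        cx = (np.arange(self.n_cols) + 0.5) * s
        cy = (np.arange(self.n_rows) + 0.5) * s
        return np.meshgrid(cx, cy)


def nestbox_greenup(x: float, y: float, grid: PixelGrid, greenup: np.ndarray,
                    fallback_radius: float = DEFAULT_FALLBACK_RADIUS):
    """Weighted green-up day for one nestbox position in one year.

    Parameters
    ----------
    greenup : per-pixel green-up days for the year, shape (n_rows, n_cols);
        NaN marks pixels without a valid estimate.

    Returns
    -------
    (value, n_pixels_used, raw_weight): the weighted mean day, the number of
    contributing pixels, and the weight mass before renormalization.
    """
    greenup = np.asarray(greenup, dtype=float)
    if greenup.shape != (grid.n_rows, grid.n_cols):
        raise InputError("greenup array shape does not match grid")
    s = grid.pixel_size
    ext_x, ext_y = grid.extent
    if not (0 <= x < ext_x and 0 <= y < ext_y):
        raise InputError(f"nestbox ({x}, {y}) outside grid extent")

    # position in pixel-center coordinates
    fx = x / s - 0.5
    fy = y / s - 0.5
    c0, r0 = int(np.floor(fx)), int(np.floor(fy))
    tx, ty = fx - c0, fy - r0

    vals, weights = [], []
    for (rr, cc, w) in ((r0, c0, (1 - tx) * (1 - ty)), (r0, c0 + 1, tx * (1 - ty)),
                        (r0 + 1, c0, (1 - tx) * ty), (r0 + 1, c0 + 1, tx * ty)):
        if not (0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols):
            continue
        g = greenup[rr, cc]
        if not np.isfinite(g):
            continue
        w_full = w * grid.woodland_fraction[rr, cc]
        if w_full > 0:
            vals.append(g)
            weights.append(w_full)

    raw = float(sum(weights))
    if raw > 0:
        vals = np.asarray(vals)
        weights = np.asarray(weights) / raw
        return float(weights @ vals), len(vals), raw

    # fallback: nearest valid woodland pixel within fallback_radius
    cx, cy = grid.centers()
    valid = np.isfinite(greenup) & (grid.woodland_fraction > 0.5)
    if valid.any():
        d2 = (cx - x) ** 2 + (cy - y) ** 2
        d2 = np.where(valid, d2, np.inf)
        idx = np.unravel_index(np.argmin(d2), d2.shape)
        if np.sqrt(d2[idx]) <= fallback_radius:
            return float(greenup[idx]), 1, 0.0
    raise NotAssignableError(
        f"nestbox at ({x:.0f}, {y:.0f}) has no valid woodland neighbour")


def nestbox_greenup_table(nestboxes: pd.DataFrame, greenup_map: pd.DataFrame,
                          grid: PixelGrid,
                          fallback_radius: float = DEFAULT_FALLBACK_RADIUS) -> pd.DataFrame:
    """Nestbox-specific green-up for every box and year in a green-up map table.

    Boxes that are not assignable in a year are omitted (counted in the log).
    """
    years = np.sort(greenup_map["year"].unique())
    rows = []
    n_drop = 0
    for year in years:
        sub = greenup_map[(greenup_map["year"] == year) & greenup_map["converged"]]
        arr = np.full((grid.n_rows, grid.n_cols), np.nan)
        pid = sub["pixel_id"].to_numpy(dtype=int)
        arr[pid // grid.n_cols, pid % grid.n_cols] = sub["greenup_day"].to_numpy(dtype=float)
        for box in nestboxes.itertuples(index=False):
            try:
                val, n_used, raw = nestbox_greenup(box.x, box.y, grid, arr,
                                                   fallback_radius=fallback_radius)
            except NotAssignableError:
                n_drop += 1
                continue
            rows.append({"box_id": box.box_id, "year": int(year), "greenup_day": val,
                         "n_pixels_used": n_used, "total_weight_raw": raw})
    if n_drop:
        logger.info("nestbox weighting: %d box-years not assignable", n_drop)
    return pd.DataFrame(rows, columns=["box_id", "year", "greenup_day",
                                       "n_pixels_used", "total_weight_raw"])


def oak_density(box_xy, tree_xy, radius: float = 75.0) -> np.ndarray:
    """Number of oak trees within ``radius`` meters (inclusive) of each box."""
    box_xy = np.atleast_2d(np.asarray(box_xy, dtype=float))
    tree_xy = np.asarray(tree_xy, dtype=float)
    if tree_xy.size == 0:
        counts = np.zeros(len(box_xy), dtype=int)
        return counts if len(counts) > 1 else int(counts[0])
    tree_xy = np.atleast_2d(tree_xy)
    from scipy.spatial import cKDTree

    tree = cKDTree(tree_xy)
    counts = np.array([len(tree.query_ball_point(p, radius)) for p in box_xy])
    return counts if len(counts) > 1 else int(counts[0])
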