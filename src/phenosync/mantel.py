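"""Mantel correlograms: spatial autocorrelation profiles with permutation tests.

For each distance class the statistic is the (negated) Pearson correlation,
over all site pairs, between the value dissimilarity |v_i - v_j| and the 0/1
indicator of the pair falling in that class.  Negation makes positive r mean
positive spatial autocorrelation (nearby sites more similar), the convention
correlograms are read in.  Significance is by permuting site labels of the
value vector; p-values are two-sided on |r|.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .errors import InputError


@dataclass
class Correlogram:
    """Distance-class Mantel statistics with permutation p-values."""

    table: pd.DataFrame  # class_lo, class_hi, r, p, n_pairs
    n_permutations: int
    seed: int | None
    method: str

    def __iter__(self):
        return iter(self.table.itertuples(index=False))


def _class_edges_equal_count(dists: np.ndarray, n_classes: int | None = None):
    """Half-open distance bins with (approximately) equal pair counts.

    The default class count follows Sturges' rule on the number of pairs.
    """
    m = dists.size
    if n_classes is None:
        n_classes = max(2, int(np.ceil(np.log2(m) + 1)))
    qs = np.quantile(dists, np.linspace(0, 1, n_classes + 1))
    edges = np.unique(qs)
    edges[-1] = edges[-1] + 1e-9  # include the farthest pair in the last class
    return edges


def _mantel_r_all_classes(dvals: np.ndarray, indicators: np.ndarray) -> np.ndarray:
    """Negated Pearson r between the dissimilarity vector and each class
    indicator vector; NaN where undefined (constant input)."""
    m = dvals.size
    dc = dvals - dvals.mean()
    sd_d = np.sqrt((dc @ dc) / m)
    out = np.full(indicators.shape[0], np.nan)
    if sd_d == 0:
        return out
    for k, ind in enumerate(indicators):
        pk = ind.mean()
        if pk in (0.0, 1.0):
            continue
        sd_i = np.sqrt(pk * (1 - pk))
        out[k] = -(dc @ (ind - pk)) / (m * sd_d * sd_i)
    return out


def mantel_correlogram(coords, values, class_edges=None, n_classes=None,
                       n_perm: int = 999, seed: int | None = 0,
                       method: str = "montecarlo", holm: bool = False) -> Correlogram:
    """Mantel correlogram of a 1-D value over 2-D site coordinates.

    Parameters
    ----------
    coords : (n, 2) site coordinates (projected meters).
    values : length-n values (e.g. laying-date residuals, pixel synchrony).
    class_edges : optional explicit distance-class edges; half-open bins
        [lo, hi).  Default: equal-count classes, Sturges' number.
    n_perm : Monte-Carlo permutations (ignored for ``method="exact"``).
    method : "montecarlo" or "exact" (all n! value permutations; only
        sensible for n <= 8).
    holm : apply a progressive Holm correction across classes.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if coords.shape[0] != n:
        raise InputError("coords and values length mismatch")
    if n < 4:
        raise InputError("need >= 4 sites")

    dgeo = pdist(coords)
    if class_edges is None:
        class_edges = _class_edges_equal_count(dgeo, n_classes)
    class_edges = np.asarray(class_edges, dtype=float)
    if np.any(np.diff(class_edges) <= 0):
        raise InputError("class edges must be strictly increasing")
    n_cls = class_edges.size - 1
    indicators = np.stack([(dgeo >= class_edges[k]) & (dgeo < class_edges[k + 1])
                           for k in range(n_cls)]).astype(float)
    n_pairs = indicators.sum(axis=1).astype(int)

    dvals = pdist(values[:, None])
    r_obs = _mantel_r_all_classes(dvals, indicators)

    defined = np.isfinite(r_obs)
    if method == "exact":
        count = np.zeros(n_cls)
        total = math.factorial(n)
        for perm in itertools.permutations(range(n)):
            dp = pdist(values[list(perm), None])
            rp = _mantel_r_all_classes(dp, indicators)
            count += np.where(defined & np.isfinite(rp),
                              np.abs(rp) >= np.abs(r_obs) - 1e-12, 0)
        p = np.where(defined, count / total, np.nan)
        n_used = total
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        count = np.zeros(n_cls)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            dp = pdist(values[perm, None])
            rp = _mantel_r_all_classes(dp, indicators)
            count += np.where(defined & np.isfinite(rp),
                              np.abs(rp) >= np.abs(r_obs) - 1e-12, 0)
        p = np.where(defined, (count + 1) / (n_perm + 1), np.nan)
        n_used = n_perm
    else:
        raise InputError("method must be 'montecarlo' or 'exact'")

    if holm:
        order = np.argsort(-np.nan_to_num(np.abs(r_obs), nan=-1))
        m_def = int(defined.sum())
        adj = p.copy()
        running = 0.0
        rank = 0
        for idx in order:
            if not defined[idx]:
                continue
            rank += 1
            running = max(running, min(1.0, (m_def - rank + 1) * p[idx]))
            adj[idx] = running
        p = adj

    table = pd.DataFrame({
        "class_lo": class_edges[:-1], "class_hi": class_edges[1:],
        "r": r_obs, "p": p, "n_pairs": n_pairs,
    })
    return Correlogram(table=table, n_permutations=n_used, seed=seed, method=method)
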