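"""Linear mixed models with crossed random intercepts, by profiled REML.

The breeding models need random intercepts for year and nestbox (optionally
female), which are crossed, not nested.  The model is

    y = X beta + Z u + e,   u_k ~ N(0, sigma^2 theta_k^2 I),  e ~ N(0, sigma^2 I)

with one block of ``u`` per grouping factor.  For fixed relative standard
deviations theta the penalized least-squares system (the mixed-model
equations with the scaled random effects) is solved by one dense Cholesky
factorization, which also yields the two log-determinants of the profiled
REML deviance; ``beta``, ``sigma^2`` and the BLUPs then come for free.  The
deviance is minimized over log(theta) by Nelder-Mead.  This is the standard
profiled formulation (as in lme4); with the modest number of random levels
here (years + nestboxes + females, ~10^3) the dense factorization is fast.

Inference on the fixed effects uses the large-sample normal approximation on
t = beta / SE; no MCMC or Satterthwaite machinery is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse, stats

from .errors import InputError

_THETA_FLOOR = 1e-6  # relative sd below which a component is flagged singular


@dataclass
class MixedLMResult:
    """REML fit of a random-intercepts linear mixed model."""

    params: pd.Series
    bse: pd.Series
    vcov: dict            # variance component per random factor
    sigma2: float         # residual variance
    theta: dict           # relative sds at the optimum
    reml_criterion: float  # -2 * restricted log-likelihood
    nobs: int
    converged: bool
    singular: bool        # any variance component at the zero boundary
    ranef: dict = field(default_factory=dict)
    fittedvalues: np.ndarray | None = None

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.tvalues.to_numpy())),
                         index=self.params.index)

    @property
    def resid(self) -> np.ndarray:
        return self._y - self.fittedvalues

    def summary_dict(self) -> dict:
        return {
            "coefficients": {
                name: {"estimate": float(self.params[name]), "se": float(self.bse[name]),
                       "t": float(self.tvalues[name]), "p": float(self.pvalues[name])}
                for name in self.params.index},
            "variance_components": {k: float(v) for k, v in self.vcov.items()},
            "residual_variance": float(self.sigma2),
            "n": int(self.nobs),
            "converged": bool(self.converged),
            "singular": bool(self.singular),
        }


def _codes(values) -> tuple[np.ndarray, np.ndarray]:
    codes, levels = pd.factorize(np.asarray(values), sort=True)
    if (codes < 0).any():
        raise InputError("random factor contains missing values")
    return codes, levels


def fit_mixed_lm(y, X, random: dict, names=None, theta0=None,
                 fixed_theta: bool = False) -> MixedLMResult:
    """Fit a linear mixed model with independent random intercepts per factor.

    Parameters
    ----------
    y : response vector.
    X : fixed-effects design matrix (include the intercept column yourself)
        or DataFrame (column names become coefficient names).
    random : mapping factor name -> label array (length n); each factor
        contributes one random-intercept block.
    theta0 : optional starting relative sds per factor.
    fixed_theta : solve at ``theta0`` without optimizing (used for
        invariance diagnostics at a common covariance).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if not random:
        raise InputError("at least one random factor is required")
    if n != y.size:
        raise InputError("X and y length mismatch")

    factor_names = list(random)
    codes_list, levels_list, qs = [], [], []
    for fname in factor_names:
        codes, levels = _codes(random[fname])
        if len(levels) < 2:
            raise InputError(f"random factor {fname!r} needs >= 2 levels")
        codes_list.append(codes)
        levels_list.append(levels)
        qs.append(len(levels))
    offsets = np.concatenate([[0], np.cumsum(qs)])
    qtot = int(offsets[-1])

    rows = np.tile(np.arange(n), len(qs))
    cols = np.concatenate([codes_list[k] + offsets[k] for k in range(len(qs))])
    Z = sparse.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, qtot))
    ZtZ = (Z.T @ Z).toarray()
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    block_of = np.repeat(np.arange(len(qs)), qs)
    nd = n - p

    def solve_at(theta):
        lam = np.asarray(theta, dtype=float)[block_of]
        A = np.empty((qtot + p, qtot + p))
        A[:qtot, :qtot] = ZtZ * np.outer(lam, lam)
        A[:qtot, :qtot][np.diag_indices(qtot)] += 1.0
        A[:qtot, qtot:] = lam[:, None] * ZtX
        A[qtot:, :qtot] = A[:qtot, qtot:].T
        A[qtot:, qtot:] = XtX
        rhs = np.concatenate([lam * Zty, Xty])
        L = linalg.cholesky(A, lower=True)
        sol = linalg.cho_solve((L, True), rhs)
        r2 = max(yty - rhs @ sol, 1e-12)
        return L, sol, r2, lam

    def neg2reml(log_theta):
        try:
            L, _, r2, _ = solve_at(np.exp(log_theta))
        except linalg.LinAlgError:  # pragma: no cover - pathological theta
            return 1e12
        d = np.log(np.diag(L))
        return (2 * d[:qtot].sum() + 2 * d[qtot:].sum()
                + nd * (1 + np.log(2 * np.pi * r2 / nd)))

    if theta0 is None:
        theta0 = np.ones(len(qs))
    else:
        theta0 = np.asarray([theta0[f] if isinstance(theta0, dict) else theta0[k]
                             for k, f in enumerate(factor_names)], dtype=float)
    theta0 = np.maximum(theta0, _THETA_FLOOR)

    if fixed_theta:
        theta = theta0
        converged = True
    else:
        res = optimize.minimize(neg2reml, np.log(theta0), method="Nelder-Mead",
                                options=dict(xatol=1e-8, fatol=1e-10, maxiter=4000))
        best_x = res.x
        # polish near-zero components onto the boundary (REML optima at
        # variance zero are approached only asymptotically by Nelder-Mead)
        for k in range(len(qs)):
            if np.exp(best_x[k]) < 0.05:
                trial = best_x.copy()
                trial[k] = np.log(_THETA_FLOOR)
                if neg2reml(trial) <= neg2reml(best_x) + 1e-10:
                    best_x = trial
        theta = np.exp(best_x)
        converged = bool(res.success)

    L, sol, r2, lam = solve_at(theta)
    beta = sol[qtot:]
    u_scaled = sol[:qtot]
    b = lam * u_scaled  # BLUPs on the data scale
    sigma2 = r2 / nd
    RX = L[qtot:, qtot:]
    covb = sigma2 * linalg.cho_solve((RX, True), np.eye(p))
    bse = np.sqrt(np.diag(covb))

    d = np.log(np.diag(L))
    crit = 2 * d[:qtot].sum() + 2 * d[qtot:].sum() + nd * (1 + np.log(2 * np.pi * r2 / nd))

    ranef = {}
    for k, fname in enumerate(factor_names):
        vals = b[offsets[k]:offsets[k + 1]]
        ranef[fname] = pd.Series(vals, index=levels_list[k])
    fitted = X @ beta + Z @ b

    result = MixedLMResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        vcov={f: float(sigma2 * theta[k] ** 2) for k, f in enumerate(factor_names)},
        sigma2=float(sigma2),
        theta={f: float(theta[k]) for k, f in enumerate(factor_names)},
        reml_criterion=float(crit),
        nobs=n,
        converged=converged,
        singular=bool((theta < 10 * _THETA_FLOOR).any()),
        ranef=ranef,
        fittedvalues=np.asarray(fitted).ravel(),
    )
    result._y = y
    return result
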