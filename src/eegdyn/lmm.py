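"""Random-intercept linear mixed models by profiled REML.

The cluster-inference stage refits the model ``y = X b + u_participant + e``
tens of thousands of times inside the bootstrap, so the single variance
component is profiled out analytically instead of calling a generic mixed
-model optimizer.  With ``V = I + g Z Z'`` (g the ratio of intercept to
residual variance) the grouped structure gives closed forms::

    a' V^-1 b = a'b - sum_j c_j (sum_{i in j} a_i)(sum_{i in j} b_i),
    c_j = g / (1 + g n_j),        log|V| = sum_j log(1 + g n_j)

so the REML criterion ``(n-p) log(r'V^-1 r) + log|V| + log|X'V^-1 X|`` is a
1-D function of g, minimized by grid search plus golden-section refinement.
The bootstrap path evaluates it for many resampled predictor vectors at
once.  ``statsmodels.MixedLM`` fits the same model and serves as the
reference implementation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_GRID = np.concatenate([[0.0], np.logspace(-3.0, 3.0, 25)])


@dataclass
class LmmFit:
    """Result of one random-intercept REML fit."""

    params: np.ndarray  # fixed-effect estimates
    bse: np.ndarray  # their standard errors
    tvalues: np.ndarray
    sigma2: float  # residual variance
    gamma: float  # variance ratio var(intercept)/var(residual)
    nobs: int
    df_resid: int
    converged: bool

    @property
    def re_var(self) -> float:
        return self.gamma * self.sigma2

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        from scipy import stats

        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return np.column_stack([self.params - q * self.bse, self.params + q * self.bse])


def group_codes(groups) -> tuple[np.ndarray, np.ndarray]:
    """Integer group codes and per-group sizes."""
    codes, _ = pd.factorize(np.asarray(groups))
    nj = np.bincount(codes).astype(float)
    return codes, nj


class _P2Stats:
    """Sufficient statistics for designs [1, x] with shared outcome y."""

    def __init__(self, y: np.ndarray, X: np.ndarray, codes: np.ndarray, nj: np.ndarray):
        self.n = y.size
        self.nj = nj
        J = nj.size
        onehot = np.zeros((self.n, J))
        onehot[np.arange(self.n), codes] = 1.0
        self.Sy = float(y.sum())
        self.Syy = float(y @ y)
        self.Gy = y @ onehot  # (J,)
        self.Sx = X.sum(axis=1)  # (R,)
        self.Sxx = np.einsum("rn,rn->r", X, X)
        self.Sxy = X @ y
        self.Gx = X @ onehot  # (R, J)


def _eval_p2(gamma: np.ndarray, st: _P2Stats) -> dict[str, np.ndarray]:
    """REML criterion and GLS solution for per-replicate variance ratios."""
    g = np.asarray(gamma, dtype=float)[:, None]  # (R, 1)
    nj = st.nj[None, :]
    c = g / (1.0 + g * nj)  # (R, J)
    a11 = st.n - (c * nj * nj).sum(axis=1)
    a12 = st.Sx - (c * nj * st.Gx).sum(axis=1)
    a22 = st.Sxx - (c * st.Gx**2).sum(axis=1)
    b1 = st.Sy - (c * nj * st.Gy[None, :]).sum(axis=1)
    b2 = st.Sxy - (c * st.Gx * st.Gy[None, :]).sum(axis=1)
    q = st.Syy - (c * st.Gy[None, :] ** 2).sum(axis=1)
    det = a11 * a22 - a12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta1 = (a22 * b1 - a12 * b2) / det
        beta2 = (a11 * b2 - a12 * b1) / det
        rss = q - beta1 * b1 - beta2 * b2
        logdetV = np.log1p(g * nj).sum(axis=1)
        crit = (st.n - 2) * np.log(rss) + logdetV + np.log(det)
        sigma2 = rss / (st.n - 2)
        se = np.sqrt(sigma2 * a11 / det)
        t = beta2 / se
    bad = ~np.isfinite(rss) | (rss <= 0) | (det <= 0)
    crit = np.where(bad, np.inf, crit)
    t = np.where(bad, np.nan, t)
    return {"crit": crit, "t": t, "beta": beta2, "se": se,
            "sigma2": sigma2, "intercept": beta1}


def fit_slope_many(
    y: np.ndarray,
    X: np.ndarray,
    codes: np.ndarray,
    nj: np.ndarray,
    grid: np.ndarray = _GRID,
    refine_iters: int = 18,
) -> dict[str, np.ndarray]:
    """REML t statistics of the slope for many predictor vectors at once.

    ``y``: (n,) shared outcome; ``X``: (R, n) predictor replicates;
    the design of each replicate is ``[1, X[r]]`` with random intercepts by
    ``codes``.  Returns slope estimates, standard errors, t values, and the
    selected variance ratio per replicate.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    st = _P2Stats(y, X, codes, nj)
    R = X.shape[0]
    crits = np.stack([_eval_p2(np.full(R, g), st)["crit"] for g in grid])  # (G, R)
    best = np.argmin(crits, axis=0)
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, grid.size - 1)]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    m1 = hi - invphi * (hi - lo)
    m2 = lo + invphi * (hi - lo)
    f1 = _eval_p2(m1, st)["crit"]
    f2 = _eval_p2(m2, st)["crit"]
    for _ in range(refine_iters):
        take1 = f1 < f2
        hi = np.where(take1, m2, hi)
        lo = np.where(take1, lo, m1)
        m1 = hi - invphi * (hi - lo)
        m2 = lo + invphi * (hi - lo)
        f1 = _eval_p2(m1, st)["crit"]
        f2 = _eval_p2(m2, st)["crit"]
    gamma = (lo + hi) / 2.0
    out = _eval_p2(gamma, st)
    out["gamma"] = gamma
    return out


class _BootStats:
    """Sufficient statistics for all (window, replicate) pairs at once."""

    def __init__(self, Y: np.ndarray, X: np.ndarray, codes: np.ndarray,
                 nj: np.ndarray):
        self.n = Y.shape[1]
        self.nj = nj
        J = nj.size
        onehot = np.zeros((self.n, J))
        onehot[np.arange(self.n), codes] = 1.0
        self.Sy = Y.sum(axis=1)  # (W,)
        self.Syy = np.einsum("wn,wn->w", Y, Y)
        self.Gy = Y @ onehot  # (W, J)
        self.Sx = X.sum(axis=1)  # (R,)
        self.Sxx = np.einsum("rn,rn->r", X, X)
        self.Gx = X @ onehot  # (R, J)
        self.Sxy = X @ Y.T  # (R, W)


def _eval_boot(gamma, st: _BootStats) -> dict[str, np.ndarray]:
    """GLS/REML quantities for scalar gamma or per-(replicate, window) gamma."""
    nj = st.nj
    if np.ndim(gamma) == 0:
        c = gamma / (1.0 + gamma * nj)  # (J,)
        a11 = st.n - (c * nj * nj).sum()
        a12 = st.Sx - st.Gx @ (c * nj)  # (R,)
        a22 = st.Sxx - st.Gx**2 @ c
        b1 = st.Sy - st.Gy @ (c * nj)  # (W,)
        q = st.Syy - st.Gy**2 @ c
        b2 = st.Sxy - st.Gx @ (c[:, None] * st.Gy.T)  # (R, W)
        logdetV = np.log1p(gamma * nj).sum()
        a11 = np.broadcast_to(a11, a12.shape)
        a12, a22 = a12[:, None], a22[:, None]
        a11 = a11[:, None]
        b1, q = b1[None, :], q[None, :]
    else:
        g = np.asarray(gamma)[..., None]  # (R, W, 1)
        c = g / (1.0 + g * nj)  # (R, W, J)
        a11 = st.n - c @ (nj * nj)
        a12 = st.Sx[:, None] - np.einsum("rwj,rj->rw", c * nj, st.Gx)
        a22 = st.Sxx[:, None] - np.einsum("rwj,rj->rw", c, st.Gx**2)
        b1 = st.Sy[None, :] - np.einsum("rwj,wj->rw", c * nj, st.Gy)
        q = st.Syy[None, :] - np.einsum("rwj,wj->rw", c, st.Gy**2)
        b2 = st.Sxy - np.einsum("rwj,rj,wj->rw", c, st.Gx, st.Gy)
        logdetV = np.log1p(g * nj).sum(axis=-1)
    det = a11 * a22 - a12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta2 = (a11 * b2 - a12 * b1) / det
        beta1 = (a22 * b1 - a12 * b2) / det
        rss = q - beta1 * b1 - beta2 * b2
        crit = (st.n - 2) * np.log(rss) + logdetV + np.log(det)
        se = np.sqrt(rss / (st.n - 2) * a11 / det)
        t = beta2 / se
    bad = ~np.isfinite(rss) | (rss <= 0) | (det <= 0)
    return {"crit": np.where(bad, np.inf, crit), "t": np.where(bad, np.nan, t),
            "beta": beta2, "se": se}


def fit_slope_boot(
    Y: np.ndarray,
    X: np.ndarray,
    codes: np.ndarray,
    nj: np.ndarray,
    grid: np.ndarray = _GRID,
    refine_iters: int = 12,
) -> dict[str, np.ndarray]:
    """REML slope t statistics for every (window, replicate) combination.

    ``Y``: (W, n) per-window outcomes; ``X``: (R, n) predictor replicates.
    Returns arrays of shape (R, W).  Same estimator as
    :func:`fit_slope_many`, evaluated jointly for speed.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    st = _BootStats(Y, X, codes, nj)
    crits = np.stack([_eval_boot(g, st)["crit"] for g in grid])  # (G, R, W)
    best = np.argmin(crits, axis=0)
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, grid.size - 1)]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    m1 = hi - invphi * (hi - lo)
    m2 = lo + invphi * (hi - lo)
    f1 = _eval_boot(m1, st)["crit"]
    f2 = _eval_boot(m2, st)["crit"]
    for _ in range(refine_iters):
        take1 = f1 < f2
        hi = np.where(take1, m2, hi)
        lo = np.where(take1, lo, m1)
        m1 = hi - invphi * (hi - lo)
        m2 = lo + invphi * (hi - lo)
        f1 = _eval_boot(m1, st)["crit"]
        f2 = _eval_boot(m2, st)["crit"]
    gamma = (lo + hi) / 2.0
    out = _eval_boot(gamma, st)
    out["gamma"] = gamma
    return out


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups,
    grid: np.ndarray = _GRID,
) -> LmmFit:
    """REML fit of ``y = X b + u_group + e`` for a general small design.

    ``X``: (n, p) including the intercept column.  The variance ratio is
    profiled on a log-spaced grid and refined by bounded 1-D minimization.
    """
    from scipy.optimize import minimize_scalar

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    codes, nj = group_codes(groups)
    J = nj.size
    onehot = np.zeros((n, J))
    onehot[np.arange(n), codes] = 1.0
    GX = X.T @ onehot  # (p, J)
    Gy = y @ onehot
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def quantities(g: float):
        c = g / (1.0 + g * nj)  # (J,)
        XtVX = XtX - (GX * c) @ GX.T
        XtVy = Xty - (GX * c) @ Gy
        ytVy = yty - (c * Gy**2).sum()
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return None
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - beta @ XtVy
        if not np.isfinite(rss) or rss <= 0:
            return None
        logdetV = np.log1p(g * nj).sum()
        crit = (n - p) * np.log(rss) + logdetV + logdet_xvx
        return crit, beta, rss, XtVX

    def crit_only(g: float) -> float:
        q = quantities(g)
        return np.inf if q is None else q[0]

    crits = [crit_only(g) for g in grid]
    i = int(np.argmin(crits))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    converged = True
    if hi > lo:
        res = minimize_scalar(crit_only, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        gamma = float(res.x) if res.fun <= crits[i] else float(grid[i])
        converged = bool(res.success) or res.fun <= crits[i]
    else:
        gamma = float(grid[i])
    q = quantities(gamma)
    if q is None:
        return LmmFit(
            params=np.full(p, np.nan), bse=np.full(p, np.nan),
            tvalues=np.full(p, np.nan), sigma2=np.nan, gamma=gamma,
            nobs=n, df_resid=n - p, converged=False,
        )
    _, beta, rss, XtVX = q
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(XtVX)
    bse = np.sqrt(np.diag(cov))
    return LmmFit(
        params=beta, bse=bse, tvalues=beta / bse, sigma2=float(sigma2),
        gamma=float(gamma), nobs=n, df_resid=n - p, converged=converged,
    )
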