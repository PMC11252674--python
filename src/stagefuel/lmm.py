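"""Maximum-likelihood linear mixed model with a single random intercept.

The climate-window scan refits the same small model (condition ~ window mean
[+ mean^2] + (1 | year)) thousands of times, so this module implements the
one-way random-intercept LMM directly instead of going through a generic
mixed-model fitter.  With a single grouping factor the covariance is
``V_j = sigma_e^2 (I + lambda J)`` per group (``lambda = sigma_u^2/sigma_e^2``,
``J`` the all-ones matrix), and Woodbury's identity reduces every GLS solve to
group-level sufficient statistics.  The profile log-likelihood is then a
smooth scalar function of ``lambda`` that is maximised by bounded search.

Estimates agree with statsmodels' MixedLM (ML) to optimizer tolerance; the
test suite checks this equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["LMMResult", "fit_lmm_ml", "aicc"]


def aicc(llf: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = AIC + 2k(k+1)/(n - k - 1) with AIC = -2 llf + 2k.
    """
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class LMMResult:
    """Fitted random-intercept model ``y = X beta + u[group] + eps``."""

    beta: np.ndarray
    sigma_u: float
    sigma_e: float
    llf: float
    n: int
    k: int                     # parameter count: p + 2, or p + 1 if sigma_u == 0
    converged: bool = True
    group_effects: dict = field(default_factory=dict)   # BLUPs by group label

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.k, self.n)

    def predict_fixed(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta


class _Suff:
    """Group-level sufficient statistics for the profile likelihood."""

    def __init__(self, X: np.ndarray, y: np.ndarray, idx: np.ndarray, n_groups: int):
        self.n, self.p = X.shape
        self.J = n_groups
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # per-group column sums of X and y
        self.sx = np.zeros((n_groups, self.p))
        for j in range(self.p):
            self.sx[:, j] = np.bincount(idx, weights=X[:, j], minlength=n_groups)
        self.sy = np.bincount(idx, weights=y, minlength=n_groups)
        self.nj = np.bincount(idx, minlength=n_groups).astype(float)


def _profile(suff: _Suff, lam: float):
    """Profile ML log-likelihood at variance ratio ``lam``; returns (llf, beta, s2, c)."""
    c = lam / (1.0 + lam * suff.nj)                      # Woodbury weights per group
    XtAX = suff.XtX - (suff.sx * c[:, None]).T @ suff.sx
    XtAy = suff.Xty - suff.sx.T @ (c * suff.sy)
    ytAy = suff.yty - float(c @ suff.sy**2)
    beta = np.linalg.solve(XtAX, XtAy)
    rss = ytAy - 2.0 * beta @ XtAy + beta @ XtAX @ beta
    rss = max(rss, 1e-300)
    n = suff.n
    s2 = rss / n
    llf = -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0) \
        - 0.5 * float(np.sum(np.log1p(lam * suff.nj)))
    return llf, beta, s2, c


def fit_lmm_ml(X, y, groups) -> LMMResult:
    """Fit ``y = X beta + u[group] + eps`` by maximum likelihood.

    Parameters
    ----------
    X : (n, p) design matrix including the intercept column.
    y : (n,) response.
    groups : (n,) group labels (any hashable values).

    If the variance-ratio estimate collapses to the boundary the model is
    refit as ordinary least squares (``sigma_u = 0``) and the OLS parameter
    count (p + 1) is used, as an OLS fit has one fewer variance component.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels, idx = np.unique(np.asarray(groups), return_inverse=True)
    suff = _Suff(X, y, idx, len(labels))

    # profile likelihood over log(lambda); also evaluate the OLS boundary
    def nll(loglam: float) -> float:
        return -_profile(suff, np.exp(loglam))[0]

    res = minimize_scalar(nll, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    llf_lam, beta, s2, c = _profile(suff, lam)
    llf0, beta0, s20, _ = _profile(suff, 0.0)

    p = X.shape[1]
    if llf0 >= llf_lam - 1e-10 or lam < 1e-10:
        # boundary: plain OLS
        return LMMResult(beta=beta0, sigma_u=0.0, sigma_e=float(np.sqrt(s20)),
                         llf=llf0, n=suff.n, k=p + 1,
                         group_effects={lab: 0.0 for lab in labels})
    # BLUPs: E[u_j | y] = c_j * (S_yj - n_j * xbar_j' beta) with c = lam/(1+lam n_j)
    resid_sums = suff.sy - suff.sx @ beta
    blup = c * resid_sums
    return LMMResult(beta=beta, sigma_u=float(np.sqrt(lam * s2)),
                     sigma_e=float(np.sqrt(s2)), llf=llf_lam, n=suff.n, k=p + 2,
                     group_effects=dict(zip(labels.tolist(), blup.tolist())))
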