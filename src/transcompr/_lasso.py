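"""L1-penalized logistic regression by IRLS + coordinate descent.

Minimizes  (1/n) * sum_i -loglik_i(b0 + x_i'beta) + lam * sum_j pf_j*|beta_j|

over a decreasing lambda sequence with warm starts.  ``pf`` are per-feature
penalty factors; a factor of 0 leaves that feature unpenalized (used for
demographic covariates that should be controlled for, not competed away).
The intercept is never penalized.  Coefficients are exactly zero at and
above the per-feature threshold, which is what stability selection counts.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _sweep(X, w, r, beta, lam, pf, n, active_only, active):
    """One coordinate-descent sweep; returns the largest coefficient change."""
    p = X.shape[1]
    max_change = 0.0
    for j in range(p):
        if active_only and not active[j]:
            continue
        xj = X[:, j]
        denom = (w * xj * xj).sum() / n
        if denom <= 0.0:
            continue
        rho = (w * xj * r).sum() / n + denom * beta[j]
        thr = lam * pf[j]
        if rho > thr:
            bnew = (rho - thr) / denom
        elif rho < -thr:
            bnew = (rho + thr) / denom
        else:
            bnew = 0.0
        diff = bnew - beta[j]
        if diff != 0.0:
            r -= diff * xj
            beta[j] = bnew
            active[j] = bnew != 0.0 or pf[j] == 0.0
            if abs(diff) > max_change:
                max_change = abs(diff)
    return max_change


@njit(cache=False)
def _path(X, y, lambdas, pf, max_outer, max_inner, tol):
    n, p = X.shape
    nlam = lambdas.shape[0]
    coefs = np.zeros((nlam, p))
    icepts = np.zeros(nlam)
    beta = np.zeros(p)
    active = np.zeros(p, dtype=np.bool_)
    for j in range(p):
        active[j] = pf[j] == 0.0
    ybar = y.mean()
    b0 = np.log(ybar / (1.0 - ybar))
    for li in range(nlam):
        lam = lambdas[li]
        for _outer in range(max_outer):
            # quadratic (working-response) approximation at current fit
            eta = b0 + X @ beta
            pvec = 1.0 / (1.0 + np.exp(-eta))
            for i in range(n):
                if pvec[i] < 1e-5:
                    pvec[i] = 1e-5
                elif pvec[i] > 1.0 - 1e-5:
                    pvec[i] = 1.0 - 1e-5
            w = pvec * (1.0 - pvec)
            z = eta + (y - pvec) / w
            r = z - b0 - X @ beta
            wsum = w.sum()
            outer_change = 0.0
            for inner in range(max_inner):
                d0 = (w * r).sum() / wsum
                b0 += d0
                r -= d0
                # full sweep first (lets features enter), then iterate the
                # active set only — the glmnet strategy
                full = inner == 0
                ch = _sweep(X, w, r, beta, lam, pf, n, not full, active)
                if abs(d0) > ch:
                    ch = abs(d0)
                if inner == 0 or ch > outer_change:
                    outer_change = ch
                if ch < tol:
                    break
            if outer_change < tol * 10.0:
                break
            big = False
            for j in range(p):
                if abs(beta[j]) > 1e3:
                    big = True
            if big:  # quasi-separated region; stop refining
                break
        coefs[li] = beta
        icepts[li] = b0
    return icepts, coefs


def lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    pf: np.ndarray,
    n_lambdas: int = 30,
    min_ratio: float = 0.01,
) -> np.ndarray:
    """Decreasing log-spaced grid from the smallest all-zero lambda."""
    n = X.shape[0]
    ybar = y.mean()
    grad = np.abs(X.T @ (y - ybar)) / n
    penalized = pf > 0
    if not penalized.any():
        raise ValueError("no penalized features; lambda grid undefined")
    lam_max = float((grad[penalized] / pf[penalized]).max())
    if lam_max <= 0:
        lam_max = 1e-3
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max * min_ratio), n_lambdas
    )


def logistic_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    pf: np.ndarray,
    max_outer: int = 10,
    max_inner: int = 50,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the penalized path; returns (intercepts, coefficients) per lambda."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    pf = np.asarray(pf, dtype=np.float64)
    if y.min() < 0 or y.max() > 1:
        raise ValueError("y must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; model undefined")
    return _path(X, y, lambdas, pf, max_outer, max_inner, tol)


def binomial_deviance(
    icepts: np.ndarray, coefs: np.ndarray, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Out-of-sample binomial deviance for every lambda on the path."""
    eta = icepts[None, :] + X @ coefs.T  # n x nlam
    pvec = 1.0 / (1.0 + np.exp(-eta))
    pvec = np.clip(pvec, 1e-10, 1 - 1e-10)
    ll = y[:, None] * np.log(pvec) + (1 - y)[:, None] * np.log(1 - pvec)
    return -2.0 * ll.sum(axis=0)
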