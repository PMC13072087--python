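"""Phylogenetic generalized least squares under the Pagel lambda model.

Model
-----
For tip data ``y`` (n species) and design matrix ``X`` (intercept + slope),

    y = X beta + eps,    eps ~ N(0, sigma^2 * V_lambda)

where ``V_lambda`` is the phylogenetic variance-covariance matrix with its
off-diagonal entries multiplied by Pagel's lambda.  ``lambda`` is estimated by
maximizing the profile log-likelihood over [0, 1] (kappa and delta implicitly
fixed at 1: branch lengths are used as-is apart from the lambda rescaling);
``beta`` and ``sigma^2`` are the GLS/ML estimates at the fitted lambda.

All linear algebra goes through Cholesky factorization of ``V_lambda``
("whitening"); the covariance matrix is never explicitly inverted.
Significance of the slope is a two-sided t test with ``n - 2`` degrees of
freedom using the unbiased residual variance, and r^2 is computed in the
whitened space against a GLS intercept-only null, matching the conventions of
standard PGLS summaries (e.g. the R package caper).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylo import Phylogeny, PhyloCovariance, lambda_transform, prune, vcv

__all__ = ["PGLSFit", "gls_profile", "fit_pgls_lambda", "r_squared", "slope_test"]

_SIGMA2_FLOOR = 1e-12  # keeps loglik finite on (near-)perfect fits
_LAMBDA_XATOL = 1e-6


@dataclass
class PGLSFit:
    """A fitted lambda-model PGLS regression.

    Attributes
    ----------
    lambda_hat:
        ML estimate of Pagel's lambda, in [0, 1].
    beta:
        (intercept, slope) in response units.
    sigma2_hat:
        ML estimate of the Brownian rate parameter.
    loglik:
        Maximized log-likelihood.
    r2:
        1 - RSS/TSS in whitened space (GLS intercept-only null).
    p_slope:
        Two-sided t-test p-value for the slope, df = n - 2.
    se_slope:
        Standard error of the slope (unbiased residual variance).
    n:
        Number of species used.
    converged:
        False if the optimizer failed and an endpoint fit was returned.
    degenerate:
        True when the fit hit the sigma^2 floor or a zero slope SE.
    """

    lambda_hat: float
    beta: np.ndarray
    sigma2_hat: float
    loglik: float
    r2: float
    p_slope: float
    se_slope: float
    n: int
    converged: bool = True
    degenerate: bool = False

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    @property
    def slope(self) -> float:
        return float(self.beta[1])


def _whiten(V: np.ndarray):
    """Cholesky factor of V; raises with the condition number if singular."""
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        cond = np.linalg.cond(V)
        raise np.linalg.LinAlgError(
            f"covariance matrix is singular or indefinite "
            f"(condition number {cond:.3g})"
        ) from exc
    return L


def gls_profile(
    y: np.ndarray, X: np.ndarray, V: PhyloCovariance | np.ndarray
) -> tuple[np.ndarray, float, float]:
    """GLS estimates and ML log-likelihood for fixed covariance V.

    Returns ``(beta, sigma2, loglik)`` with

        beta   = (X' V^-1 X)^-1 X' V^-1 y        (GLS)
        sigma2 = (y - X beta)' V^-1 (y - X beta) / n   (ML)

    computed via the Cholesky factor L of V (solving triangular systems,
    never forming V^-1).  Collinear designs raise ``LinAlgError`` with the
    design's condition number.
    """
    Vm = V.matrix if isinstance(V, PhyloCovariance) else np.asarray(V)
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.shape[0]
    L = _whiten(Vm)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    q, r = np.linalg.qr(Xw)
    if np.abs(np.diag(r)).min() < 1e-12 * max(1.0, np.abs(np.diag(r)).max()):
        raise np.linalg.LinAlgError(
            f"design matrix is collinear (condition number {np.linalg.cond(Xw):.3g})"
        )
    beta = linalg.solve_triangular(r, q.T @ yw, lower=False)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    sigma2 = max(rss / n, _SIGMA2_FLOOR)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * logdetV - 0.5 * n
    return beta, sigma2, loglik


def r_squared(
    y: np.ndarray, X: np.ndarray, beta: np.ndarray, V: PhyloCovariance | np.ndarray
) -> float:
    """Coefficient of determination in the whitened space.

    ``1 - RSS/TSS`` where both sums of squares are computed after whitening
    by the Cholesky factor of V, and TSS uses the GLS intercept-only
    (phylogenetic mean) fit under the same V.  Returns 0 with a warning when
    TSS vanishes (constant response).
    """
    Vm = V.matrix if isinstance(V, PhyloCovariance) else np.asarray(V)
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    L = _whiten(Vm)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    ones_w = linalg.solve_triangular(L, np.ones_like(y), lower=True)
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    tss = float(np.sum((yw - ones_w * mu) ** 2))
    if tss <= 1e-12 * max(float(yw @ yw), 1e-300):
        warnings.warn("constant response: r^2 defined as 0", stacklevel=2)
        return 0.0
    return max(0.0, min(1.0, 1.0 - rss / tss))


def slope_test(
    y: np.ndarray, X: np.ndarray, beta: np.ndarray, V: PhyloCovariance | np.ndarray
) -> tuple[float, float, float]:
    """Two-sided t test for the slope coefficient.

    Uses the unbiased residual variance RSS_w / (n - 2) and the usual GLS
    coefficient covariance ``sigma2 * (X' V^-1 X)^-1``; df = n - 2.

    Returns ``(p_value, se_slope, t_stat)``.  A zero SE (perfectly collinear
    or perfect fit) gives p = 0 and is flagged by the caller.
    """
    Vm = V.matrix if isinstance(V, PhyloCovariance) else np.asarray(V)
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > {p} observations for a slope test, got {n}")
    L = _whiten(Vm)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    resid = yw - Xw @ beta
    s2 = float(resid @ resid) / (n - p)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = float(np.sqrt(max(s2 * XtX_inv[1, 1], 0.0)))
    if se == 0.0:
        return 0.0, 0.0, np.inf if beta[1] != 0 else 0.0
    t = float(beta[1]) / se
    pval = 2.0 * float(stats.t.sf(abs(t), df=n - p))
    return pval, se, t


def profile_loglik(
    lam: float, y: np.ndarray, X: np.ndarray, cov: PhyloCovariance
) -> float:
    """Profile log-likelihood of lambda (beta, sigma^2 maximized out)."""
    _, _, ll = gls_profile(y, X, lambda_transform(cov, lam))
    return ll


def fit_pgls_lambda(
    y,
    x,
    tree: Phylogeny | PhyloCovariance,
    *,
    species: list[str] | None = None,
) -> PGLSFit:
    """Fit a simple PGLS regression with lambda estimated by ML.

    Parameters
    ----------
    y, x:
        Response and predictor.  Either mappings/Series keyed by species
        label, or arrays aligned with ``species`` (or with the covariance
        taxa when ``tree`` is a precomputed :class:`PhyloCovariance`).
    tree:
        Phylogeny whose tips cover the data species (extra tips are pruned
        away), or a ready covariance matrix.
    species:
        Explicit species order for array inputs.

    Species missing from either variable (NaN) are dropped pairwise and the
    tree is re-pruned accordingly.

    Raises
    ------
    ValueError
        If fewer than 4 complete cases remain or species are missing from
        the tree (message lists the mismatches).
    """
    y_map = _as_series(y, species)
    x_map = _as_series(x, species)
    common = [s for s in y_map.index if s in set(x_map.index)]
    data = pd.DataFrame({"y": y_map.loc[common], "x": x_map.loc[common]}).dropna()
    if isinstance(tree, PhyloCovariance):
        tip_set = set(tree.taxa)
    else:
        tip_set = set(tree.tip_labels)
    missing = sorted(set(data.index) - tip_set)
    if missing:
        raise ValueError(f"species absent from the tree: {missing}")
    if len(data) < 4:
        raise ValueError(f"need at least 4 complete cases, got {len(data)}")

    taxa = list(data.index)
    if isinstance(tree, PhyloCovariance):
        cov = tree.reorder(taxa)
    else:
        sub = prune(tree, set(taxa)) if len(taxa) < tree.n_tips else tree
        cov = vcv(sub).reorder(taxa)

    yv = data["y"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(data)), data["x"].to_numpy(dtype=float)])

    nll = lambda lam: -profile_loglik(lam, yv, X, cov)
    candidates: list[float] = [0.0, 1.0]
    converged = True
    for lo, hi in [(0.0, 1.0), (0.0, 0.5), (0.25, 0.75), (0.5, 1.0)]:
        res = optimize.minimize_scalar(
            nll, bounds=(lo, hi), method="bounded",
            options={"xatol": _LAMBDA_XATOL},
        )
        if res.success:
            candidates.append(float(res.x))
        else:
            converged = False
    lam_hat = min(candidates, key=nll)

    V_lam = lambda_transform(cov, lam_hat)
    beta, sigma2, loglik = gls_profile(yv, X, V_lam)
    r2 = r_squared(yv, X, beta, V_lam)
    pval, se, _ = slope_test(yv, X, beta, V_lam)
    degenerate = sigma2 <= _SIGMA2_FLOOR or se == 0.0
    return PGLSFit(
        lambda_hat=lam_hat,
        beta=beta,
        sigma2_hat=sigma2,
        loglik=loglik,
        r2=r2,
        p_slope=pval,
        se_slope=se,
        n=len(data),
        converged=converged,
        degenerate=degenerate,
    )


def _as_series(v, species: list[str] | None) -> pd.Series:
    if isinstance(v, pd.Series):
        return v
    if isinstance(v, dict):
        return pd.Series(v)
    arr = np.asarray(v, dtype=float)
    if species is None:
        raise ValueError("array input requires an explicit `species` order")
    if len(arr) != len(species):
        raise ValueError("length of data and species order differ")
    return pd.Series(arr, index=list(species))
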