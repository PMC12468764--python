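"""L1-penalized linear regression by cyclic coordinate descent.

The statistical engine of the pipeline.  Minimizes

    (1 / 2n) * sum_i (y_i - b0 - x_i' b)^2  +  lambda * sum_j |b_j|

by cyclic coordinate descent with soft-thresholding, over a geometric
regularization path with warm starts, selecting lambda by K-fold
cross-validation that minimizes mean validation MSE.  Predictors are
internally centered and scaled to unit (population) variance; coefficients
are reported on the original scale and the intercept is never penalized.

The inner solver works on the Gram matrix G = X'X/n (covariance updates),
which makes the per-sweep cost O(p^2) independent of n and lets the hot loop
be compiled with numba.  A pure-Python mirror of the kernel exists both as a
debug engine (it checks that the objective never increases) and as a
reference implementation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

try:  # compiled hot loop; the pure-Python mirror is used when unavailable
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f
        return wrap


logger = logging.getLogger(__name__)

__all__ = ["LassoConfig", "LassoFit", "lasso_fit", "lambda_path", "cv_select_lambda"]


@dataclass(frozen=True)
class LassoConfig:
    """Solver and cross-validation settings (glmnet-style defaults)."""

    n_lambda: int = 100
    #: smallest path value as a fraction of lambda_max; None = 0.01 if n < p else 1e-4
    lambda_min_ratio: float | None = None
    cv_folds: int = 10
    standardize: bool = True
    penalize_site: bool = True
    max_iter: int = 100_000
    #: stop a sweep cycle when max_j v_j * (delta beta_j)^2 < tol, with v_j the
    #: (standardized) column variance — the glmnet-style threshold
    tol: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    def min_ratio(self, n: int, p: int) -> float:
        if self.lambda_min_ratio is not None:
            return self.lambda_min_ratio
        return 0.01 if n < p else 1e-4


@dataclass(frozen=True)
class LassoFit:
    """One fitted model: coefficients on the original predictor scale."""

    intercept: float
    coefficients: np.ndarray
    lam: float
    converged: bool

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients


# ---------------------------------------------------------------------------
# kernels

@njit(cache=True)
def _sweep(G, c, diag, penalty, lam, beta, gb, active_only):  # pragma: no cover
    p = G.shape[0]
    max_delta = 0.0
    for j in range(p):
        if diag[j] <= 0.0:
            continue
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        rho = c[j] - gb[j] + diag[j] * bj
        thr = lam * penalty[j]
        if rho > thr:
            bn = (rho - thr) / diag[j]
        elif rho < -thr:
            bn = (rho + thr) / diag[j]
        else:
            bn = 0.0
        d = bn - bj
        if d != 0.0:
            beta[j] = bn
            for k in range(p):
                gb[k] += G[k, j] * d
            wd = diag[j] * d * d
            if wd > max_delta:
                max_delta = wd
    return max_delta


@njit(cache=True)
def _cd_path_kernel(G, c, diag, penalty, lambdas, tol, max_iter):  # pragma: no cover
    p = G.shape[0]
    n_lam = lambdas.shape[0]
    betas = np.zeros((n_lam, p))
    conv = np.ones(n_lam, dtype=np.bool_)
    beta = np.zeros(p)
    gb = np.zeros(p)  # G @ beta, maintained incrementally
    for li in range(n_lam):
        lam = lambdas[li]
        it = 0
        converged = False
        while it < max_iter:
            # full sweep over all coordinates (also the convergence check)
            max_delta = _sweep(G, c, diag, penalty, lam, beta, gb, False)
            it += 1
            if max_delta < tol:
                converged = True
                break
            # refine on the current active (nonzero) set until stable
            while it < max_iter:
                max_delta = _sweep(G, c, diag, penalty, lam, beta, gb, True)
                it += 1
                if max_delta < tol:
                    break
        conv[li] = converged
        betas[li] = beta
    return betas, conv


def _objective(G, c, y_var, beta, lam, penalty):
    """(1/2n)||y~ - X~ b||^2 + lam * sum penalty_j |b_j|, via Gram identities."""
    quad = 0.5 * (y_var - 2.0 * c @ beta + beta @ G @ beta)
    return float(quad + lam * np.sum(penalty * np.abs(beta)))


def _cd_path_python(G, c, diag, penalty, lambdas, tol, max_iter, y_var=None, debug=False):
    """Pure-Python mirror of the kernel; with debug=True asserts that the
    objective is non-increasing across every 10th sweep."""
    p = G.shape[0]
    betas = np.zeros((len(lambdas), p))
    conv = np.ones(len(lambdas), dtype=bool)
    beta = np.zeros(p)
    gb = np.zeros(p)

    def sweep(lam, active_only):
        max_delta = 0.0
        for j in range(p):
            if diag[j] <= 0.0 or (active_only and beta[j] == 0.0):
                continue
            bj = beta[j]
            rho = c[j] - gb[j] + diag[j] * bj
            thr = lam * penalty[j]
            if rho > thr:
                bn = (rho - thr) / diag[j]
            elif rho < -thr:
                bn = (rho + thr) / diag[j]
            else:
                bn = 0.0
            d = bn - bj
            if d != 0.0:
                beta[j] = bn
                gb[:] = gb + G[:, j] * d
                max_delta = max(max_delta, diag[j] * d * d)
        return max_delta

    for li, lam in enumerate(lambdas):
        last_obj = np.inf
        it = 0
        converged = False
        while it < max_iter:
            max_delta = sweep(lam, False)
            it += 1
            if debug:
                obj = _objective(G, c, y_var, beta, lam, penalty)
                assert obj <= last_obj + 1e-10, "objective increased"
                last_obj = obj
            if max_delta < tol:
                converged = True
                break
            while it < max_iter:
                max_delta = sweep(lam, True)
                it += 1
                if debug and (it % 10 == 0):
                    obj = _objective(G, c, y_var, beta, lam, penalty)
                    assert obj <= last_obj + 1e-10, "objective increased"
                    last_obj = obj
                if max_delta < tol:
                    break
        conv[li] = converged
        betas[li] = beta
    return betas, conv


# ---------------------------------------------------------------------------
# standardization plumbing

class _Scaled:
    """Centered/standardized view of (X, y) plus back-transformation."""

    def __init__(self, X: np.ndarray, y: np.ndarray, config: LassoConfig):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D and row-aligned with 1-D y")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 observations")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite entries in X or y")
        self.n, self.p = X.shape
        self.x_mean = X.mean(axis=0)
        sd = X.std(axis=0)  # population (1/n) SD, consistent with lambda_max
        self.constant = sd == 0.0
        if config.standardize:
            self.x_scale = np.where(self.constant, 1.0, sd)
        else:
            self.x_scale = np.ones(self.p)
        self.y_mean = y.mean()
        Xs = (X - self.x_mean) / self.x_scale
        ys = y - self.y_mean
        self.G = (Xs.T @ Xs) / self.n
        self.c = (Xs.T @ ys) / self.n
        self.diag = np.where(self.constant, 0.0, np.diag(self.G))
        self.y_var = float(ys @ ys) / self.n
        self.penalty = np.ones(self.p)
        if not config.penalize_site and self.p > 0:
            # site covariate is by convention the last design column
            self.penalty[-1] = 0.0

    def lambda_max(self) -> float:
        pen = self.penalty > 0
        if not np.any(pen):
            return 0.0
        return float(np.max(np.abs(self.c[pen])))

    def to_original(self, betas_std: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map standardized-scale path solutions to original scale + intercepts."""
        b = betas_std / self.x_scale
        b0 = self.y_mean - b @ self.x_mean
        return b, b0


def _solve_path(scaled: _Scaled, lambdas: np.ndarray, config: LassoConfig,
                debug: bool = False) -> tuple[np.ndarray, np.ndarray]:
    lambdas = np.asarray(lambdas, dtype=float)
    if debug or not _HAVE_NUMBA:
        return _cd_path_python(
            scaled.G, scaled.c, scaled.diag, scaled.penalty, lambdas,
            config.tol, config.max_iter, y_var=scaled.y_var, debug=debug,
        )
    return _cd_path_kernel(
        scaled.G, scaled.c, scaled.diag, scaled.penalty, lambdas,
        float(config.tol), int(config.max_iter),
    )


# ---------------------------------------------------------------------------
# public operations

def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    config: LassoConfig = LassoConfig(),
    debug: bool = False,
) -> LassoFit:
    """Fit the LASSO at a single penalty value ``lam`` (>= 0).

    Coefficients come back on the original predictor scale; constant columns
    receive coefficient exactly 0; the intercept is unpenalized.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    scaled = _Scaled(X, y, config)
    betas, conv = _solve_path(scaled, np.array([lam]), config, debug=debug)
    b, b0 = scaled.to_original(betas)
    if not conv[0]:
        logger.warning("coordinate descent did not converge at lambda=%g", lam)
    return LassoFit(intercept=float(b0[0]), coefficients=b[0], lam=float(lam),
                    converged=bool(conv[0]))


def lambda_path(X: np.ndarray, y: np.ndarray, config: LassoConfig = LassoConfig()) -> np.ndarray:
    """Decreasing geometric sequence of n_lambda penalties from lambda_max down.

    lambda_max = max_j |<x~_j, y - ybar>| / n over penalized standardized
    columns — the smallest penalty at which every penalized coefficient is 0.
    A constant outcome gives lambda_max = 0 and a degenerate single-value path.
    """
    scaled = _Scaled(X, y, config)
    lam_max = scaled.lambda_max()
    if lam_max == 0.0:
        warnings.warn("constant outcome (or no penalized columns): degenerate path {0}")
        return np.array([0.0])
    ratio = config.min_ratio(scaled.n, scaled.p)
    return lam_max * np.power(ratio, np.linspace(0.0, 1.0, config.n_lambda))


def _fold_ids(n: int, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    ids = np.arange(n) % k
    return ids[rng.permutation(n)]


def cv_lasso(
    X: np.ndarray,
    y: np.ndarray,
    config: LassoConfig = LassoConfig(),
) -> tuple[float, LassoFit, pd.DataFrame]:
    """Cross-validated lambda selection plus the full-data fit at the optimum.

    Folds are assigned by a seeded shuffle; every fold is scored on the shared
    full-data path; the selected lambda minimizes mean validation MSE, with
    ties broken toward the larger (sparser) lambda.  Returns
    ``(lambda_opt, fit_at_opt, cv_curve)`` where the curve has columns
    ``lam``, ``mean_mse``, ``se_mse``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    k = min(config.cv_folds, n)
    if k < config.cv_folds:
        logger.debug("reducing cv folds from %d to n=%d", config.cv_folds, n)
    if k < 2:
        raise ValueError("need at least 2 observations for cross-validation")
    path = lambda_path(X, y, config)
    ids = _fold_ids(n, k, config.seed)

    fold_mse = np.full((k, len(path)), np.nan)
    n_degenerate = 0
    for f in range(k):
        val = ids == f
        Xtr, ytr = X[~val], y[~val]
        Xva, yva = X[val], y[val]
        if Xtr.shape[0] < 2 or np.all(ytr == ytr[0]):
            # degenerate training fold: intercept-only model, still scored
            n_degenerate += 1
            preds = np.full((Xva.shape[0], len(path)), ytr.mean() if len(ytr) else 0.0)
        else:
            scaled = _Scaled(Xtr, ytr, config)
            betas, _ = _solve_path(scaled, path, config)
            b, b0 = scaled.to_original(betas)
            preds = Xva @ b.T + b0
        fold_mse[f] = np.mean((preds - yva[:, None]) ** 2, axis=0)
    if n_degenerate == k:
        raise ValueError("all cross-validation folds degenerate")

    mean_mse = fold_mse.mean(axis=0)
    se_mse = fold_mse.std(axis=0, ddof=1) / np.sqrt(k)
    # path is stored decreasing, so argmin's first-occurrence rule prefers
    # the larger lambda on ties
    best = int(np.argmin(mean_mse))
    lam_opt = float(path[best])
    fit = lasso_fit(X, y, lam_opt, config)
    curve = pd.DataFrame({"lam": path, "mean_mse": mean_mse, "se_mse": se_mse})
    return lam_opt, fit, curve


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    config: LassoConfig = LassoConfig(),
) -> tuple[float, pd.DataFrame]:
    """The MSE-minimizing lambda and the cross-validation curve."""
    lam_opt, _, curve = cv_lasso(X, y, config)
    return lam_opt, curve
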