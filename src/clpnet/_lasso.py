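"""Partially-penalized LASSO by cyclic coordinate descent on Gram matrices.

Solves, for standardized designs,

    min_{b0, beta}  (1/2n) * ||y - b0 - X beta||^2  +  lambda * sum_{j in P} |beta_j|

where P is the set of penalized columns; covariate columns (gender, age) and
the intercept are never penalized.  The solver works on the Gram form
(G = X'X/n, c = X'y/n) so a full regularization path with warm starts costs
O(p^2) per sweep regardless of n — cheap enough that bootstrap procedures
can re-estimate whole networks thousands of times.

The inner kernel is JIT-compiled with numba when available and falls back to
the identical pure-Python loop otherwise.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _cd_gram(G, c, beta, lam, penalized, tol, max_iter):  # pragma: no cover - numba
    """Cyclic coordinate descent on the Gram form; updates ``beta`` in place.

    Returns the number of sweeps used, or -1 on non-convergence.
    """
    p = G.shape[0]
    for sweep in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj <= 0.0:
                beta[j] = 0.0
                continue
            # partial residual correlation for coordinate j
            r = c[j] - np.dot(G[j], beta) + gjj * beta[j]
            if penalized[j]:
                if r > lam:
                    b_new = (r - lam) / gjj
                elif r < -lam:
                    b_new = (r + lam) / gjj
                else:
                    b_new = 0.0
            else:
                b_new = r / gjj
            delta = abs(b_new - beta[j])
            if delta > max_delta:
                max_delta = delta
            beta[j] = b_new
        if max_delta < tol:
            return sweep + 1
    return -1


def _check_finite(name, arr):
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")


def _center(y, X):
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    return y - y_mean, X - x_mean, y_mean, x_mean


def _penalized_mask(p, unpenalized_cols):
    mask = np.ones(p, dtype=np.bool_)
    for j in unpenalized_cols:
        mask[int(j)] = False
    return mask


def lasso_path(
    y,
    X,
    lam: float,
    unpenalized_cols=(),
    tol: float = 1e-8,
    max_iter: int = 100_000,
    beta_init=None,
):
    """Solve the partially-penalized LASSO at a single penalty value.

    Returns ``(intercept, beta)``.  The intercept and any column listed in
    ``unpenalized_cols`` carry no penalty.  Raises on non-finite input or
    non-convergence at ``max_iter`` sweeps.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    _check_finite("y", y)
    _check_finite("X", X)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = X.shape
    yc, Xc, y_mean, x_mean = _center(y, X)
    G = (Xc.T @ Xc) / n
    c = (Xc.T @ yc) / n
    beta = np.zeros(p) if beta_init is None else np.asarray(beta_init, dtype=float).copy()
    mask = _penalized_mask(p, unpenalized_cols)
    sweeps = _cd_gram(G, c, beta, float(lam), mask, float(tol), int(max_iter))
    if sweeps < 0:
        raise RuntimeError(f"coordinate descent did not converge in {max_iter} sweeps")
    intercept = y_mean - float(x_mean @ beta)
    return intercept, beta


def lambda_max(y, X, unpenalized_cols=()):
    """Smallest penalty that zeroes every penalized coefficient.

    With unpenalized covariates present, the KKT bound is taken on the
    residual of y after the unpenalized-only fit (including intercept).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    mask = _penalized_mask(p, unpenalized_cols)
    yc, Xc, _, _ = _center(y, X)
    if (~mask).any():
        U = Xc[:, ~mask]
        coef, *_ = np.linalg.lstsq(U, yc, rcond=None)
        resid = yc - U @ coef
    else:
        resid = yc
    scores = np.abs(Xc[:, mask].T @ resid) / n
    return float(scores.max()) if scores.size else 0.0


def _path_gram(G, c, lambdas, mask, tol, max_iter):
    """Warm-started coefficient path over a decreasing lambda grid."""
    p = G.shape[0]
    betas = np.empty((len(lambdas), p))
    beta = np.zeros(p)
    for k, lam in enumerate(lambdas):
        sweeps = _cd_gram(G, c, beta, float(lam), mask, float(tol), int(max_iter))
        if sweeps < 0:
            raise RuntimeError(
                f"coordinate descent did not converge at lambda={lam:.3g}"
            )
        betas[k] = beta
    return betas


def _fold_assignment(n, n_folds, seed):
    """Seeded permutation split into n_folds near-equal contiguous blocks."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    sizes = np.full(n_folds, n // n_folds, dtype=np.int64)
    sizes[: n % n_folds] += 1
    start = 0
    for f, size in enumerate(sizes):
        folds[perm[start : start + size]] = f
        start += size
    return folds


class CVResult:
    """Cross-validation curve and selected penalty for one outcome."""

    __slots__ = ("lambdas", "mean_error", "se_error", "lambda_min", "lambda_1se", "selected", "folds")

    def __init__(self, lambdas, mean_error, se_error, lambda_min, lambda_1se, selected, folds):
        self.lambdas = lambdas
        self.mean_error = mean_error
        self.se_error = se_error
        self.lambda_min = lambda_min
        self.lambda_1se = lambda_1se
        self.selected = selected
        self.folds = folds


def cv_select_lambda(
    y,
    X,
    unpenalized_cols=(),
    n_folds: int = 10,
    lambda_rule: str = "1se",
    n_lambda: int = 50,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    seed: int = 0,
    folds=None,
) -> CVResult:
    """K-fold cross-validation over a log-spaced penalty grid.

    The grid runs from the full-data ``lambda_max`` down to
    ``lambda_max * lambda_min_ratio``; folds come from one seeded
    permutation (or a caller-supplied assignment, so all node regressions of
    a network can share folds).  ``lambda_rule`` picks the minimum-CV-error
    penalty (``"min"``) or the largest penalty within one standard error of
    it (``"1se"``).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    _check_finite("y", y)
    _check_finite("X", X)
    n, p = X.shape
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} rows, got {n}")
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")

    lam_max = lambda_max(y, X, unpenalized_cols)
    if lam_max <= 0:  # no penalized signal at all; degenerate grid
        lam_max = 1e-12
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    mask = _penalized_mask(p, unpenalized_cols)

    if folds is None:
        folds = _fold_assignment(n, n_folds, seed)
    else:
        folds = np.asarray(folds)
        if folds.shape != (n,):
            raise ValueError("fold assignment must have one entry per row")

    fold_err = np.empty((n_folds, n_lambda))
    for f in range(n_folds):
        test = folds == f
        Xtr, ytr = X[~test], y[~test]
        Xte, yte = X[test], y[test]
        ytr_c, Xtr_c, y_mean, x_mean = _center(ytr, Xtr)
        ntr = len(ytr)
        G = (Xtr_c.T @ Xtr_c) / ntr
        c = (Xtr_c.T @ ytr_c) / ntr
        betas = _path_gram(G, c, lambdas, mask, tol, max_iter)
        pred = (Xte - x_mean) @ betas.T + y_mean
        fold_err[f] = ((yte[:, None] - pred) ** 2).mean(axis=0)

    mean_error = fold_err.mean(axis=0)
    se_error = fold_err.std(axis=0, ddof=1) / np.sqrt(n_folds)
    k_min = int(np.argmin(mean_error))
    lambda_min = float(lambdas[k_min])
    within = mean_error <= mean_error[k_min] + se_error[k_min]
    lambda_1se = float(lambdas[np.flatnonzero(within).min()])
    selected = lambda_min if lambda_rule == "min" else lambda_1se
    return CVResult(lambdas, mean_error, se_error, lambda_min, lambda_1se, selected, folds)
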