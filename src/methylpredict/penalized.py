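"""Elastic-net estimation with K-fold cross-validated penalty selection.

Objective (for mixing parameter ``alpha`` in [0, 1] and penalty ``lam``):

    (1/2n) * sum((y - b0 - X b)^2)
        + lam * (alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2)

Features are standardized internally (mean 0, population sd 1) and
coefficients are reported back on the original feature scale, matching the
dominant convention of penalized-regression software. ``lam`` selection is
minimum cross-validated squared error, with ties broken toward the largest
(sparsest) ``lam``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import enet_path

from .exceptions import NumericError, ValidationError

#: number of path points and path depth (lam_max down to lam_max * ratio)
DEFAULT_N_LAMBDA = 100
DEFAULT_LAMBDA_MIN_RATIO = 1e-3
#: stand-in mixing value used to size the path when alpha == 0 (pure ridge),
#: where the true lam_max is infinite
RIDGE_ALPHA_FLOOR = 1e-3


@dataclass(frozen=True)
class FoldAssignment:
    """Balanced K-fold partition of ``n`` samples, deterministic in ``seed``."""

    n: int
    k: int
    seed: int
    membership: np.ndarray

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (train_idx, test_idx) for one fold."""
        test = np.flatnonzero(self.membership == fold)
        train = np.flatnonzero(self.membership != fold)
        return train, test


@dataclass
class ElasticNetFit:
    intercept: float
    coefficients: np.ndarray
    alpha_mix: float
    lambda_selected: float
    #: rows of (lambda, mean CV squared error, SE over folds); empty for
    #: single-lambda fits
    cv_curve: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients

    @property
    def nonzero_idx(self) -> np.ndarray:
        return np.flatnonzero(self.coefficients != 0.0)


def make_folds(n: int, k: int, seed: int) -> FoldAssignment:
    """Deterministic balanced partition: fold sizes differ by at most one."""
    if not 2 <= k <= n:
        raise ValidationError(f"fold count k={k} must satisfy 2 <= k <= n={n}")
    rng = np.random.default_rng(seed)
    membership = np.empty(n, dtype=int)
    membership[rng.permutation(n)] = np.arange(n) % k
    return FoldAssignment(n=n, k=k, seed=seed, membership=membership)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)  # constant columns stay zeroed out
    Xs = (X - mu) / sd_safe
    return Xs, mu, sd_safe


def _check_finite(X: np.ndarray, y: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite entries in X")
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite entries in y")


def _ridge_path(Xs: np.ndarray, yc: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Closed-form ridge solutions along the path via one thin SVD.

    Minimizes (1/2n)||yc - Xs b||^2 + (lam/2)||b||^2; returns
    (n_lambda, p) coefficients on the standardized scale.
    """
    n = Xs.shape[0]
    U, d, Vt = np.linalg.svd(Xs, full_matrices=False)
    uty = U.T @ yc
    # shrinkage factor d / (d^2 + n*lam) per singular value per lambda
    shrink = d[None, :] / (d[None, :] ** 2 + n * lambdas[:, None])
    return (shrink * uty[None, :]) @ Vt


def _enet_path_std(
    Xs: np.ndarray, yc: np.ndarray, alpha: float, lambdas: np.ndarray
) -> np.ndarray:
    """Coefficient path on standardized data, (n_lambda, p)."""
    if alpha == 0.0:
        return _ridge_path(Xs, yc, lambdas)
    _, coefs, _ = enet_path(
        Xs, yc, l1_ratio=alpha, alphas=lambdas, tol=1e-6, max_iter=20000
    )
    return coefs.T


def lambda_grid(
    Xs: np.ndarray,
    yc: np.ndarray,
    alpha: float,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> np.ndarray:
    """Decreasing log-spaced penalty path from the null-model threshold."""
    n = Xs.shape[0]
    alpha_eff = max(alpha, RIDGE_ALPHA_FLOOR)
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * alpha_eff)
    if lam_max <= 0 or not np.isfinite(lam_max):
        lam_max = 1.0
    ratio = lambda_min_ratio
    if alpha < RIDGE_ALPHA_FLOOR:
        # lam_max was sized with the floored alpha; deepen the path so the
        # effective floor matches the alpha > 0 case
        ratio = lambda_min_ratio * alpha_eff
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def fit_elastic_net(
    X: np.ndarray, y: np.ndarray, alpha_mix: float, lam: float
) -> ElasticNetFit:
    """Fit at a single penalty value; coefficients on the raw feature scale."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_finite(X, y)
    if not 0.0 <= alpha_mix <= 1.0:
        raise ValidationError(f"alpha_mix must be in [0, 1], got {alpha_mix}")
    Xs, mu, sd = _standardize(X)
    ybar = float(y.mean())
    yc = y - ybar
    b_std = _enet_path_std(Xs, yc, alpha_mix, np.array([lam]))[0]
    coef = b_std / sd
    coef[X.std(axis=0) == 0] = 0.0
    intercept = ybar - float(coef @ mu)
    return ElasticNetFit(
        intercept=intercept,
        coefficients=coef,
        alpha_mix=alpha_mix,
        lambda_selected=float(lam),
    )


def cv_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    alpha_mix: float,
    folds: FoldAssignment,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    lambda_path: Optional[Sequence[float]] = None,
) -> ElasticNetFit:
    """Path fit with K-fold CV penalty selection, then a full-data refit.

    The path is computed once on the full data; each fold restandardizes
    its own training portion. The selected ``lam`` minimizes mean
    out-of-fold squared error (ties -> largest ``lam``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_finite(X, y)
    n = X.shape[0]
    if folds.n != n:
        raise ValidationError(f"fold assignment is for n={folds.n}, data has n={n}")
    if n < folds.k:
        raise ValidationError("fewer samples than folds")
    if np.std(y) == 0:
        raise NumericError("target is constant; cannot cross-validate")

    Xs_full, _, _ = _standardize(X)
    if lambda_path is not None:
        lambdas = np.sort(np.asarray(lambda_path, dtype=float))[::-1]
    else:
        lambdas = lambda_grid(Xs_full, y - y.mean(), alpha_mix, n_lambda, lambda_min_ratio)

    sq_err = np.zeros((folds.k, len(lambdas)))
    fold_sizes = np.zeros(folds.k)
    for f in range(folds.k):
        tr, te = folds.fold_indices(f)
        Xs_tr, mu_tr, sd_tr = _standardize(X[tr])
        ybar_tr = y[tr].mean()
        coefs_std = _enet_path_std(Xs_tr, y[tr] - ybar_tr, alpha_mix, lambdas)
        coefs_raw = coefs_std / sd_tr[None, :]
        coefs_raw[:, X[tr].std(axis=0) == 0] = 0.0
        intercepts = ybar_tr - coefs_raw @ mu_tr
        preds = X[te] @ coefs_raw.T + intercepts[None, :]
        sq_err[f] = ((preds - y[te][:, None]) ** 2).sum(axis=0)
        fold_sizes[f] = len(te)

    mean_cv = sq_err.sum(axis=0) / n
    fold_mse = sq_err / fold_sizes[:, None]
    se_cv = fold_mse.std(axis=0, ddof=1) / np.sqrt(folds.k)
    best = int(np.argmin(mean_cv))  # first index = largest lambda on ties
    lam_sel = float(lambdas[best])

    fit = fit_elastic_net(X, y, alpha_mix, lam_sel)
    fit.cv_curve = np.column_stack([lambdas, mean_cv, se_cv])
    return fit
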