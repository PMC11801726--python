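"""Cross-validation stacking over a declarative learner library.

Every candidate learner sees identical folds; out-of-fold predictions form
the meta-learning design matrix Z, and the ensemble weights solve

    argmin_{w >= 0, sum w = 1}  mean((y - Z w)^2)

via non-negative least squares, normalization, and a simplex polish. With
the mean-only learner always in the library, the ensemble's CV risk can
never exceed the best single learner's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any, Optional, Sequence

import numpy as np
import scipy.optimize
from sklearn.linear_model import RidgeCV

from .exceptions import NumericError, ValidationError
from .penalized import FoldAssignment, cv_elastic_net, make_folds

logger = logging.getLogger(__name__)

LEARNER_FAMILIES = ("penalized_linear", "smooth_additive", "mean_only")


@dataclass(frozen=True)
class LearnerSpec:
    """Declarative description of one candidate learner.

    penalized_linear : elastic net with mixing parameter ``alpha`` and an
        internally cross-validated penalty path.
    smooth_additive : per-feature cubic-spline basis expansion (dimension
        ``basis_dim``) on the top ``top_k`` features, ridge-fitted.
    mean_only : predicts the training mean (keeps the oracle inequality
        from being vacuous).
    """

    family: str
    alpha: Optional[float] = None
    basis_dim: int = 4
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.family not in LEARNER_FAMILIES:
            raise ValidationError(f"unknown learner family {self.family!r}")
        if self.family == "penalized_linear":
            if self.alpha is None or not 0.0 <= self.alpha <= 1.0:
                raise ValidationError(
                    f"penalized_linear needs alpha in [0, 1], got {self.alpha}"
                )

    @property
    def name(self) -> str:
        if self.family == "penalized_linear":
            return f"enet_a{self.alpha:g}"
        if self.family == "smooth_additive":
            return f"smooth_k{self.top_k}_d{self.basis_dim}"
        return "mean_only"

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "alpha": self.alpha,
            "basis_dim": self.basis_dim,
            "top_k": self.top_k,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LearnerSpec":
        return cls(
            family=d["family"],
            alpha=None if d.get("alpha") is None else float(d["alpha"]),
            basis_dim=int(d.get("basis_dim", 4)),
            top_k=int(d.get("top_k", 10)),
        )


@dataclass
class CVPredictions:
    """Out-of-fold prediction matrix: Z[i, l] came from a model fit without i."""

    Z: np.ndarray
    learner_specs: list[LearnerSpec]
    folds: FoldAssignment


@dataclass
class MetaWeights:
    w: np.ndarray
    cv_risk_ensemble: float
    cv_risk_per_learner: np.ndarray


def default_library(task: str) -> list[LearnerSpec]:
    """Penalty-mixing ladder plus mean-only; complex traits add a smooth learner."""
    if task not in ("age", "complex_trait"):
        raise ValidationError(f"task must be 'age' or 'complex_trait', got {task!r}")
    specs = [LearnerSpec("penalized_linear", alpha=a) for a in (0.0, 0.25, 0.5, 0.75, 1.0)]
    specs.append(LearnerSpec("mean_only"))
    if task == "complex_trait":
        specs.append(LearnerSpec("smooth_additive"))
    return specs


# ---------------------------------------------------------------------------
# individual learner fitting


def _spline_basis(z: np.ndarray, knot: float, dim: int) -> np.ndarray:
    """Cubic spline basis on a standardized feature: z, z^2, z^3, (z-knot)^3_+ ..."""
    cols = [z, z**2, z**3]
    cols.append(np.clip(z - knot, 0.0, None) ** 3)
    return np.column_stack(cols[:dim]) if dim < 4 else np.column_stack(cols)


def _smooth_design(X: np.ndarray, params: dict) -> np.ndarray:
    cols = []
    for j, (mu, sd, knot) in enumerate(
        zip(params["mu"], params["sd"], params["knots"])
    ):
        z = (X[:, params["feature_idx"][j]] - mu) / sd
        cols.append(_spline_basis(z, knot, params["basis_dim"]))
    return np.hstack(cols)


def fit_learner(
    spec: LearnerSpec, X: np.ndarray, y: np.ndarray, seed: int, n_folds: int = 10
) -> dict[str, Any]:
    """Fit one candidate learner; returns JSON-serializable parameters."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if spec.family == "mean_only":
        return {"mean": float(y.mean())}
    if spec.family == "penalized_linear":
        k = max(2, min(n_folds, n))
        fit = cv_elastic_net(X, y, spec.alpha, make_folds(n, k, seed))
        return {
            "intercept": fit.intercept,
            "coefficients": fit.coefficients,
            "lambda_selected": fit.lambda_selected,
        }
    # smooth_additive: spline expansion of the top-k columns, ridge-fitted
    top_k = min(spec.top_k, X.shape[1])
    idx = list(range(top_k))
    sub = X[:, idx]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    knots = np.median((sub - mu) / sd, axis=0)
    params = {
        "feature_idx": idx,
        "mu": mu,
        "sd": sd,
        "knots": knots,
        "basis_dim": spec.basis_dim,
    }
    design = _smooth_design(X, params)
    ridge = RidgeCV(alphas=np.geomspace(1e-3, 1e3, 13)).fit(design, y)
    params["ridge_coef"] = ridge.coef_
    params["ridge_intercept"] = float(ridge.intercept_)
    return params


def predict_learner(spec: LearnerSpec, params: dict, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if spec.family == "mean_only":
        return np.full(X.shape[0], params["mean"], dtype=float)
    if spec.family == "penalized_linear":
        return params["intercept"] + X @ np.asarray(params["coefficients"], dtype=float)
    design = _smooth_design(X, params)
    return params["ridge_intercept"] + design @ np.asarray(params["ridge_coef"], dtype=float)


# ---------------------------------------------------------------------------
# stacking


def cross_validate_library(
    X: np.ndarray,
    y: np.ndarray,
    specs: Sequence[LearnerSpec],
    folds: FoldAssignment,
    seed: int = 0,
) -> CVPredictions:
    """Out-of-fold predictions for every learner on shared folds.

    A learner failing on any fold is dropped with a logged warning (never a
    silent zero column); only a fully failing library is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if folds.n != n:
        raise ValidationError("fold assignment does not match sample count")
    columns: list[np.ndarray] = []
    kept: list[LearnerSpec] = []
    for li, spec in enumerate(specs):
        z = np.full(n, np.nan)
        try:
            for f in range(folds.k):
                tr, te = folds.fold_indices(f)
                params = fit_learner(spec, X[tr], y[tr], seed=seed * 1000 + f)
                z[te] = predict_learner(spec, params, X[te])
            if not np.all(np.isfinite(z)):
                raise NumericError("non-finite out-of-fold predictions")
        except Exception as exc:
            logger.warning("dropping learner %s: %s", spec.name, exc)
            continue
        columns.append(z)
        kept.append(spec)
    if not kept:
        raise NumericError("every learner in the library failed")
    return CVPredictions(Z=np.column_stack(columns), learner_specs=kept, folds=folds)


def _simplex_risk(Z: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    return float(np.mean((y - Z @ w) ** 2))


def solve_meta_weights(cvp: CVPredictions, y: np.ndarray) -> MetaWeights:
    """Simplex-constrained squared-error meta-weights.

    NNLS on the out-of-fold predictions, normalized to the simplex, then
    polished with a constrained quadratic solve; if NNLS is all-zero or the
    polish cannot beat the best single learner, falls back to the discrete
    Super Learner (weight 1 on the lowest-risk learner).
    """
    y = np.asarray(y, dtype=float)
    Z = cvp.Z
    L = Z.shape[1]
    per_risk = np.mean((y[:, None] - Z) ** 2, axis=0)

    def discrete(idx: int) -> MetaWeights:
        w = np.zeros(L)
        w[idx] = 1.0
        return MetaWeights(w=w, cv_risk_ensemble=per_risk[idx], cv_risk_per_learner=per_risk)

    if np.std(y) == 0:
        for i, spec in enumerate(cvp.learner_specs):
            if spec.family == "mean_only":
                return discrete(i)
        return discrete(int(np.argmin(per_risk)))

    w_nnls, _ = scipy.optimize.nnls(Z, y)
    if w_nnls.sum() <= 0:
        return discrete(int(np.argmin(per_risk)))
    w0 = w_nnls / w_nnls.sum()

    ZtZ = Z.T @ Z / len(y)
    Zty = Z.T @ y / len(y)
    yty = float(y @ y) / len(y)

    def risk(w):
        return yty - 2.0 * w @ Zty + w @ ZtZ @ w

    def grad(w):
        return -2.0 * Zty + 2.0 * ZtZ @ w

    res = scipy.optimize.minimize(
        risk,
        w0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * L,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones(L)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    candidates = [w0]
    if res.success:
        candidates.append(np.clip(res.x, 0.0, None))
    best_w, best_risk = None, np.inf
    for cand in candidates:
        s = cand.sum()
        if s <= 0:
            continue
        cand = cand / s
        r = _simplex_risk(Z, y, cand)
        if r < best_risk:
            best_w, best_risk = cand, r
    if best_w is None or best_risk > per_risk.min() + 1e-12:
        return discrete(int(np.argmin(per_risk)))
    return MetaWeights(w=best_w, cv_risk_ensemble=best_risk, cv_risk_per_learner=per_risk)


def fit_full_library(
    X: np.ndarray, y: np.ndarray, specs: Sequence[LearnerSpec], seed: int = 0
) -> list[tuple[LearnerSpec, dict]]:
    """Refit every surviving learner on the complete training data."""
    fitted = []
    for spec in specs:
        try:
            fitted.append((spec, fit_learner(spec, X, y, seed=seed)))
        except Exception as exc:
            raise NumericError(f"refit of learner {spec.name} failed: {exc}") from exc
    return fitted


def ensemble_predict(
    fitted_learners: Sequence[tuple[LearnerSpec, dict]],
    weights: np.ndarray,
    X: np.ndarray,
) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(fitted_learners):
        raise ValidationError(
            f"{len(weights)} weights for {len(fitted_learners)} learners"
        )
    X = np.asarray(X, dtype=float)
    out = np.zeros(X.shape[0])
    for w, (spec, params) in zip(weights, fitted_learners):
        if w != 0.0:
            out += w * predict_learner(spec, params, X)
    return out
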