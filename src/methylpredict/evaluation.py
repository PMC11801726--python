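"""Fit metrics, paired bootstrap comparison, and age-acceleration analyses.

"MAE" throughout this package is the MEDIAN absolute error; the API name
embeds "median" so it cannot be confused with the mean absolute error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .datatypes import PhenotypeTable
from .exceptions import NumericError, ValidationError

Z_975 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class EvalReport:
    n: int
    pearson_r: float
    mae_median: float
    method: str = ""

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValidationError(f"correlation {self.pearson_r} outside [-1, 1]")
        if self.mae_median < 0:
            raise ValidationError("median absolute error cannot be negative")


@dataclass
class BootstrapComparison:
    method_pair: tuple[str, str]
    delta_r_point: float
    delta_r_ci_95: tuple[float, float]
    delta_mae_point: float
    delta_mae_ci_95: tuple[float, float]
    n_iterations: int
    seed: int


@dataclass
class EAAResult:
    sample_id: str
    eaa: float
    adjusted: bool


def pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    """Product-moment correlation; constant inputs are a hard error."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValidationError("pearson: length mismatch")
    if len(pred) < 3:
        raise ValidationError("pearson needs at least 3 observations")
    if np.std(pred) == 0:
        raise NumericError("pearson: predictions are constant")
    if np.std(obs) == 0:
        raise NumericError("pearson: observations are constant")
    p = pred - pred.mean()
    o = obs - obs.mean()
    return float((p @ o) / np.sqrt((p @ p) * (o @ o)))


def median_abs_error(pred: np.ndarray, obs: np.ndarray) -> float:
    """Median of |pred - obs| (even length: midpoint of the central pair)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValidationError("median_abs_error: length mismatch")
    if pred.size == 0:
        raise ValidationError("median_abs_error: empty input")
    return float(np.median(np.abs(pred - obs)))


def evaluate_predictions(pred, obs, method: str = "") -> EvalReport:
    return EvalReport(
        n=len(np.asarray(obs)),
        pearson_r=pearson(pred, obs),
        mae_median=median_abs_error(pred, obs),
        method=method,
    )


def replicate_agreement(pred: np.ndarray, pheno: PhenotypeTable, method: str = "") -> EvalReport:
    """Agreement between replicate pairs (same specimen measured twice).

    ``pred`` must be aligned to ``pheno``'s rows. Every non-null replicate
    group must have exactly two members; correlation and median absolute
    difference are computed across pairs (first member vs second member).
    """
    groups = pheno.replicate_group
    if groups is None:
        raise ValidationError("phenotype table has no replicate-group column")
    pred = np.asarray(pred, dtype=float)
    if len(pred) != len(groups):
        raise ValidationError("prediction vector not aligned to phenotype rows")
    members: dict[str, list[int]] = {}
    for i, g in enumerate(groups):
        if g is None or (isinstance(g, float) and np.isnan(g)) or str(g) == "":
            continue
        members.setdefault(str(g), []).append(i)
    bad = {g: len(ix) for g, ix in members.items() if len(ix) != 2}
    if bad:
        raise ValidationError(f"replicate groups without exactly 2 members: {bad}")
    if len(members) < 2:
        raise ValidationError("need at least 2 replicate pairs")
    first = np.array([pred[ix[0]] for ix in members.values()])
    second = np.array([pred[ix[1]] for ix in members.values()])
    if np.std(first) == 0 or np.std(second) == 0:
        raise NumericError("replicate predictions are constant; correlation undefined")
    r = float(np.corrcoef(first, second)[0, 1])
    mae = float(np.median(np.abs(first - second)))
    return EvalReport(n=len(members), pearson_r=r, mae_median=mae, method=method)


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bootstrap_compare(
    predA: np.ndarray,
    predB: np.ndarray,
    obs: np.ndarray,
    n_iter: int = 10000,
    seed: int = 0,
    method_pair: tuple[str, str] = ("A", "B"),
) -> BootstrapComparison:
    """Paired bootstrap CI for differences in correlation and median error.

    Each iteration draws one index vector with replacement and applies it
    to both prediction vectors and the observations, so the two predictors
    are always compared on identical resamples. Point deltas are the
    full-sample differences (no resampling bias); CIs are 2.5/97.5
    percentiles. Resamples with constant observations (or constant
    predictions) are redrawn, capped at 10 * n_iter total draws.
    """
    predA = np.asarray(predA, dtype=float)
    predB = np.asarray(predB, dtype=float)
    obs = np.asarray(obs, dtype=float)
    n = len(obs)
    if len(predA) != n or len(predB) != n:
        raise ValidationError("bootstrap_compare: unaligned inputs")
    if n < 10:
        raise ValidationError("bootstrap_compare needs n >= 10")

    rng = np.random.default_rng(seed)
    delta_r = np.empty(n_iter)
    delta_mae = np.empty(n_iter)
    filled = 0
    total_drawn = 0
    while filled < n_iter:
        budget = min(n_iter - filled, n_iter)
        total_drawn += budget
        if total_drawn > 10 * n_iter:
            raise NumericError("too many degenerate bootstrap resamples")
        idx = rng.integers(0, n, size=(budget, n))
        o = obs[idx]
        a = predA[idx]
        b = predB[idx]
        ra = _rowwise_pearson(a, o)
        rb = _rowwise_pearson(b, o)
        ok = np.isfinite(ra) & np.isfinite(rb)
        k = int(ok.sum())
        if k == 0:
            continue
        delta_r[filled : filled + k] = (ra - rb)[ok]
        delta_mae[filled : filled + k] = (
            np.median(np.abs(a - o), axis=1) - np.median(np.abs(b - o), axis=1)
        )[ok]
        filled += k

    return BootstrapComparison(
        method_pair=method_pair,
        delta_r_point=pearson(predA, obs) - pearson(predB, obs),
        delta_r_ci_95=(
            float(np.percentile(delta_r, 2.5)),
            float(np.percentile(delta_r, 97.5)),
        ),
        delta_mae_point=median_abs_error(predA, obs) - median_abs_error(predB, obs),
        delta_mae_ci_95=(
            float(np.percentile(delta_mae, 2.5)),
            float(np.percentile(delta_mae, 97.5)),
        ),
        n_iterations=n_iter,
        seed=seed,
    )


def compute_eaa(
    pred_age: np.ndarray,
    age: np.ndarray,
    cell_props: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Age-acceleration residuals: OLS of predicted age on chronological age.

    With cell proportions supplied they are added as covariates; if the
    columns sum to ~1 per row the last column is dropped (collinearity
    guard). Residuals have zero mean and zero covariance with every
    regressor by construction.
    """
    pred_age = np.asarray(pred_age, dtype=float)
    age = np.asarray(age, dtype=float)
    n = len(age)
    design_cols = [np.ones(n), age]
    if cell_props is not None:
        cp = np.asarray(cell_props, dtype=float)
        if cp.ndim != 2 or cp.shape[0] != n:
            raise ValidationError("cell proportion matrix not aligned to samples")
        if cp.shape[1] >= 2 and np.allclose(cp.sum(axis=1), 1.0, atol=0.02):
            cp = cp[:, :-1]
        design_cols.extend(cp.T)
    X = np.column_stack(design_cols)
    if n <= X.shape[1]:
        raise ValidationError("too few samples for the EAA regression")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise NumericError("rank-deficient EAA design matrix")
    coef, *_ = np.linalg.lstsq(X, pred_age, rcond=None)
    return pred_age - X @ coef


def associate_eaa(
    eaa: np.ndarray,
    exposure: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> tuple[float, float, float]:
    """OLS association of EAA with an exposure: (beta, classical SE, p)."""
    eaa = np.asarray(eaa, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if np.std(exposure) == 0:
        raise NumericError("exposure has zero variance")
    cols = [exposure]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    X = sm.add_constant(np.column_stack(cols))
    if len(eaa) <= X.shape[1]:
        raise ValidationError("too few samples for the association model")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise NumericError("rank-deficient association design")
    fit = sm.OLS(eaa, X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def ci_width_summary(
    fits_by_method: Mapping[str, Sequence[tuple[float, float, float]]],
) -> dict[str, float]:
    """Mean 95% Wald CI width per method from (beta, SE, p) fit tuples."""
    out = {}
    for method, fits in fits_by_method.items():
        if not fits:
            raise ValidationError(f"no fits for method {method!r}")
        out[method] = float(np.mean([2.0 * Z_975 * se for (_, se, _) in fits]))
    return out
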