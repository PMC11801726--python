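"""The three top-level predictor pipelines.

* CpG predictor: cross-validated elastic net on the beta matrix itself.
* PCA predictor: PCA -> low-variance trim -> elastic net on the scores,
  projecting new data with the training centering.
* SL PCA predictor: stacked ensemble (SuperLearner) on the full PC score
  matrix.

All three train on the transformed target and invert predictions back to
target units before any evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .datatypes import BetaMatrix, PhenotypeTable
from .exceptions import NumericError, ValidationError
from .io import align
from .models import CpGModel, PCAModel, SLModel
from .pca import fit_pca, project, trim_low_variance
from .penalized import (
    DEFAULT_LAMBDA_MIN_RATIO,
    DEFAULT_N_LAMBDA,
    cv_elastic_net,
    make_folds,
)
from .superlearner import (
    LearnerSpec,
    cross_validate_library,
    default_library,
    ensemble_predict,
    fit_full_library,
    solve_meta_weights,
)
from .transforms import AgeTransform, harmonize_probes, inverse_transform_age, transform_age

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Shared training configuration for all three pipelines."""

    alpha: float = 0.5
    n_folds: int = 10
    seed: int = 0
    age_transform: AgeTransform = field(default_factory=AgeTransform)
    trim_count: Union[int, str] = "auto"
    library: Union[str, list[LearnerSpec]] = "age"
    n_lambda: int = DEFAULT_N_LAMBDA
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO
    max_missing_frac: float = 0.2
    exclude_outliers: bool = False
    outlier_mad_k: float = 5.0

    def learner_specs(self) -> list[LearnerSpec]:
        if isinstance(self.library, str):
            return default_library(self.library)
        return list(self.library)


def _prepare_training(
    beta: BetaMatrix, pheno: PhenotypeTable, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Align, impute missing betas with column means, transform the target.

    Returns (X imputed, y transformed, probe_ids, column means).
    """
    beta, pheno = align(beta, pheno)
    y_raw = pheno.target
    if not np.all(np.isfinite(y_raw)):
        raise ValidationError("training target contains non-finite values")
    X = beta.values.copy()
    col_means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    if np.any(np.isnan(col_means)):
        raise ValidationError("some probes are missing in every training sample")
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
        logger.info("imputed %d missing beta cells with probe means", int(nan_mask.sum()))
    if np.std(y_raw) == 0:
        raise NumericError("constant training target")
    y = transform_age(y_raw, config.age_transform)
    return X, np.asarray(y, dtype=float), list(beta.probe_ids), col_means


def _mad_keep_mask(residuals: np.ndarray, k: float) -> np.ndarray:
    mad = np.median(np.abs(residuals - np.median(residuals)))
    if mad == 0:
        return np.ones(len(residuals), dtype=bool)
    return np.abs(residuals - np.median(residuals)) <= k * mad


def _cv_enet(S: np.ndarray, y: np.ndarray, config: PipelineConfig):
    """One cross-validated elastic-net fit with optional MAD outlier refit."""
    def _fit(Sf, yf):
        folds = make_folds(len(yf), min(config.n_folds, len(yf)), config.seed)
        return cv_elastic_net(
            Sf, yf, config.alpha, folds,
            n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio,
        )

    fit = _fit(S, y)
    if config.exclude_outliers:
        keep = _mad_keep_mask(y - fit.predict(S), config.outlier_mad_k)
        if not keep.all():
            logger.warning("excluding %d outlier sample(s) (>%g x MAD residual)",
                           int((~keep).sum()), config.outlier_mad_k)
            fit = _fit(S[keep], y[keep])
    return fit


def _cpg_from_prepared(
    X: np.ndarray, y: np.ndarray, probe_ids: list[str],
    col_means: np.ndarray, config: PipelineConfig,
) -> CpGModel:
    fit = _cv_enet(X, y, config)
    nz = fit.nonzero_idx
    if len(nz) == 0:
        raise NumericError(
            "elastic net selected zero probes; lower lambda_min_ratio or noise level"
        )
    return CpGModel(
        intercept=float(fit.intercept),
        coefficients={probe_ids[j]: float(fit.coefficients[j]) for j in nz},
        training_probe_means={probe_ids[j]: float(col_means[j]) for j in nz},
        target_transform=config.age_transform,
    )


def train_cpg(beta: BetaMatrix, pheno: PhenotypeTable, config: PipelineConfig) -> CpGModel:
    """Elastic net directly on probes; keeps only nonzero-coefficient probes."""
    X, y, probe_ids, col_means = _prepare_training(beta, pheno, config)
    return _cpg_from_prepared(X, y, probe_ids, col_means, config)


def predict_cpg(
    model: CpGModel, beta_new: BetaMatrix, max_missing_frac: float = 0.2
) -> np.ndarray:
    X, frac = harmonize_probes(
        model.probe_ids, beta_new, model.training_probe_means, max_missing_frac
    )
    if frac > 0:
        logger.info("predict_cpg: imputed fraction %.4f", frac)
    return inverse_transform_age(model.linear_predict(X), model.target_transform)


def _pca_from_prepared(
    X: np.ndarray, y: np.ndarray, probe_ids: list[str],
    config: PipelineConfig, full_basis=None,
) -> PCAModel:
    basis = trim_low_variance(full_basis if full_basis is not None else fit_pca(X),
                              config.trim_count)
    scores = project(basis, X)
    fit = _cv_enet(scores, y, config)
    nz = fit.nonzero_idx
    if len(nz) == 0:
        raise NumericError(
            "elastic net selected zero principal components; lower lambda_min_ratio"
        )
    return PCAModel(
        probe_ids=probe_ids,
        center=basis.center,
        rotation=basis.rotation,
        retained_pc_count=basis.n_components,
        pc_intercept=float(fit.intercept),
        pc_coefficients={int(j): float(fit.coefficients[j]) for j in nz},
        target_transform=config.age_transform,
    )


def train_pca(beta: BetaMatrix, pheno: PhenotypeTable, config: PipelineConfig) -> PCAModel:
    """PCA, low-variance trim, then elastic net on the training scores."""
    X, y, probe_ids, _ = _prepare_training(beta, pheno, config)
    return _pca_from_prepared(X, y, probe_ids, config)


def _pca_scores_for(model, beta_new: BetaMatrix, max_missing_frac: float) -> np.ndarray:
    X, frac = harmonize_probes(
        model.probe_ids, beta_new, model.training_probe_means, max_missing_frac
    )
    if frac > 0:
        logger.info("projection: imputed fraction %.4f", frac)
    return (X - model.center) @ model.rotation


def predict_pca(
    model: PCAModel, beta_new: BetaMatrix, max_missing_frac: float = 0.2
) -> np.ndarray:
    scores = _pca_scores_for(model, beta_new, max_missing_frac)
    return inverse_transform_age(model.linear_predict(scores), model.target_transform)


def _sl_from_prepared(
    X: np.ndarray, y: np.ndarray, probe_ids: list[str],
    config: PipelineConfig, full_basis=None,
) -> SLModel:
    basis = trim_low_variance(full_basis if full_basis is not None else fit_pca(X), "auto")
    scores = project(basis, X)
    folds = make_folds(len(y), min(config.n_folds, len(y)), config.seed)
    cvp = cross_validate_library(scores, y, config.learner_specs(), folds, seed=config.seed)
    meta = solve_meta_weights(cvp, y)
    fitted = fit_full_library(scores, y, cvp.learner_specs, seed=config.seed)
    return SLModel(
        probe_ids=probe_ids,
        center=basis.center,
        rotation=basis.rotation,
        fitted_learners=fitted,
        meta_weights=meta.w,
        cv_config={"n_folds": folds.k, "seed": config.seed},
        target_transform=config.age_transform,
    )


def train_sl_pca(beta: BetaMatrix, pheno: PhenotypeTable, config: PipelineConfig) -> SLModel:
    """Stacked ensemble on the full PC score matrix (zero-variance PCs dropped)."""
    X, y, probe_ids, _ = _prepare_training(beta, pheno, config)
    return _sl_from_prepared(X, y, probe_ids, config)


def train_all(
    beta: BetaMatrix, pheno: PhenotypeTable, config: PipelineConfig
) -> dict[str, Union[CpGModel, PCAModel, SLModel]]:
    """Train all three predictors, running PCA only once for the two PC-based ones."""
    X, y, probe_ids, col_means = _prepare_training(beta, pheno, config)
    full_basis = fit_pca(X)
    return {
        "cpg": _cpg_from_prepared(X, y, probe_ids, col_means, config),
        "pca": _pca_from_prepared(X, y, probe_ids, config, full_basis=full_basis),
        "slpca": _sl_from_prepared(X, y, probe_ids, config, full_basis=full_basis),
    }


def predict_any(model, beta_new: BetaMatrix, max_missing_frac: float = 0.2) -> np.ndarray:
    """Dispatch prediction on the model variant."""
    if isinstance(model, CpGModel):
        return predict_cpg(model, beta_new, max_missing_frac)
    if isinstance(model, PCAModel):
        return predict_pca(model, beta_new, max_missing_frac)
    if isinstance(model, SLModel):
        return predict_sl_pca(model, beta_new, max_missing_frac)
    raise ValidationError(f"cannot predict with {type(model).__name__}")


def predict_sl_pca(
    model: SLModel, beta_new: BetaMatrix, max_missing_frac: float = 0.2
) -> np.ndarray:
    scores = _pca_scores_for(model, beta_new, max_missing_frac)
    pred = ensemble_predict(model.fitted_learners, model.meta_weights, scores)
    return inverse_transform_age(pred, model.target_transform)


def split_train_test(
    n_samples: int,
    test_fraction: float,
    n_permutations: int = 1,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded random train/test partitions; test size = round(n * fraction).

    (round-half-even: n=673 at fraction 0.25 gives the 505/168 split.)
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError("test_fraction must be in (0, 1)")
    n_test = int(round(n_samples * test_fraction))
    if n_test < 2 or n_samples - n_test < 2:
        raise ValidationError(
            f"split of n={n_samples} at fraction {test_fraction} leaves "
            "fewer than 2 samples on one side"
        )
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_permutations):
        perm = rng.permutation(n_samples)
        test = np.sort(perm[:n_test])
        train = np.sort(perm[n_test:])
        out.append((train, test))
    return out
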