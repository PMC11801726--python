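"""Principal-component decomposition with training-centered projection.

Decomposition is a thin SVD of the centered samples x probes matrix (the
covariance route is infeasible at ~3e5 probes; results are identical).
New samples are projected with the *training* centering -- never
re-centered on the new data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np

from .exceptions import NumericError, ValidationError

#: explained-variance-ratio threshold below which "auto" trimming drops a PC
AUTO_TRIM_RATIO = 1e-10


@dataclass(frozen=True)
class PCABasis:
    """Centered PCA basis.

    center : per-probe training mean, shape (p,)
    rotation : probes x PCs loadings with unit-norm columns, ordered by
        decreasing explained variance; sign fixed so each column's
        largest-magnitude loading is positive
    explained_variance : per-PC variance (denominator n - 1)
    n_components_total : component count before any trimming
    n_trimmed : trailing components removed so far
    """

    center: np.ndarray
    rotation: np.ndarray
    explained_variance: np.ndarray
    n_components_total: int
    n_trimmed: int = 0

    @property
    def n_components(self) -> int:
        return self.rotation.shape[1]


def fit_pca(X: np.ndarray) -> PCABasis:
    """Centered thin-SVD decomposition with at most min(n-1, p) components."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite entries in PCA input (impute first)")
    center = X.mean(axis=0)
    Xc = X - center
    if np.allclose(Xc, 0.0):
        raise NumericError("constant matrix: no variance to decompose")
    U, d, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, p)
    d, Vt = d[:k], Vt[:k]
    # deterministic sign: largest-|loading| entry of each column positive
    flip = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    rotation = (Vt * flip[:, None]).T
    explained = d**2 / (n - 1)
    return PCABasis(
        center=center,
        rotation=rotation,
        explained_variance=explained,
        n_components_total=k,
        n_trimmed=0,
    )


def trim_low_variance(basis: PCABasis, trim_count: Union[int, str] = "auto") -> PCABasis:
    """Drop trailing low-variance components.

    ``"auto"`` removes components whose explained-variance ratio falls
    below 1e-10 (this always includes the exact-zero final component of a
    centered decomposition when n - 1 <= p). An integer removes exactly
    that many trailing components.
    """
    total_var = basis.explained_variance.sum()
    if trim_count == "auto":
        ratio = basis.explained_variance / total_var
        keep = int(np.sum(ratio >= AUTO_TRIM_RATIO))
        trim = basis.n_components - keep
    else:
        trim = int(trim_count)
        if trim >= basis.n_components:
            raise ValidationError(
                f"cannot trim {trim} of {basis.n_components} components"
            )
        keep = basis.n_components - trim
    if keep < 1:
        raise NumericError("trimming removed every component")
    return replace(
        basis,
        rotation=basis.rotation[:, :keep],
        explained_variance=basis.explained_variance[:keep],
        n_trimmed=basis.n_trimmed + trim,
    )


def project(basis: PCABasis, X_new: np.ndarray) -> np.ndarray:
    """Scores of new samples: (X_new - training center) @ rotation."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != basis.rotation.shape[0]:
        raise ValidationError(
            f"column count {X_new.shape[1]} does not match basis probe count "
            f"{basis.rotation.shape[0]}"
        )
    return (X_new - basis.center) @ basis.rotation
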