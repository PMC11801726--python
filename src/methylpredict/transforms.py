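"""Target transformations and probe-space harmonization.

The childhood age transform maps years onto a log scale anchored at an
adult "knot" age (default 21): ``log(age + 1) - log(knot + 1)``. Training
happens on the transformed scale; predictions are inverted back to years
before any correlation or error metric is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .datatypes import BetaMatrix
from .exceptions import NumericError, ValidationError

WEEKS_PER_YEAR = 52.1429
FULL_TERM_WEEKS = 39.0


@dataclass(frozen=True)
class AgeTransform:
    """Forward/inverse target transform.

    kind : ``"identity"`` or ``"log_child"``
    adult_age_knot : anchor age in years for the log transform (21 by default).
    """

    kind: str = "identity"
    adult_age_knot: float = 21.0

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "log_child"):
            raise ValidationError(f"unknown age transform kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "adult_age_knot": self.adult_age_knot}

    @classmethod
    def from_dict(cls, d: Mapping) -> "AgeTransform":
        return cls(kind=d["kind"], adult_age_knot=float(d.get("adult_age_knot", 21.0)))


def gestational_to_years(ga_weeks, bounds: tuple[float, float] = (20.0, 45.0)):
    """Convert gestational age (weeks) to age in years relative to full term.

    ``years = -((39 - GA) / 52.1429)``; GA below 39 weeks yields a negative
    age. Out-of-bounds GA warns but still returns the computed value.
    """
    ga = np.asarray(ga_weeks, dtype=float)
    lo, hi = bounds
    if np.any((ga < lo) | (ga > hi)):
        warnings.warn(
            f"gestational age outside plausible bounds [{lo}, {hi}] weeks; "
            "returning the computed value anyway",
            UserWarning,
            stacklevel=2,
        )
    out = -((FULL_TERM_WEEKS - ga) / WEEKS_PER_YEAR) + 0.0  # avoid -0.0
    return float(out) if np.isscalar(ga_weeks) else out


def transform_age(age_years, t: AgeTransform):
    """Apply the forward target transform (years -> model scale)."""
    age = np.asarray(age_years, dtype=float)
    if t.kind == "identity":
        out = age.copy()
    else:
        if np.any(age <= -1.0):
            raise NumericError("log_child transform requires age > -1 year")
        out = np.log(age + 1.0) - np.log(t.adult_age_knot + 1.0)
    return float(out) if np.isscalar(age_years) else out


def inverse_transform_age(x, t: AgeTransform):
    """Invert :func:`transform_age` (model scale -> years)."""
    v = np.asarray(x, dtype=float)
    if t.kind == "identity":
        out = v.copy()
    else:
        out = np.exp(v + np.log(t.adult_age_knot + 1.0)) - 1.0
    return float(out) if np.isscalar(x) else out


def harmonize_probes(
    model_probes: Sequence[str],
    beta: BetaMatrix,
    means: Mapping[str, float],
    max_missing_frac: float = 0.2,
) -> tuple[np.ndarray, float]:
    """Reorder/impute a beta matrix into a model's probe space.

    Columns come out in ``model_probes`` order. Probes absent from ``beta``
    and individual missing cells are filled with the training means.
    Returns ``(matrix, imputed_fraction)``; an imputed fraction above
    ``max_missing_frac`` is a hard error.
    """
    missing_means = [p for p in model_probes if p not in means]
    if missing_means:
        raise ValidationError(
            f"training means absent for {len(missing_means)} model probe(s), "
            f"e.g. {missing_means[:3]}"
        )
    idx = beta.probe_index()
    n, p = beta.n_samples, len(model_probes)
    out = np.empty((n, p), dtype=float)
    imputed = 0
    for j, probe in enumerate(model_probes):
        col_idx = idx.get(probe)
        if col_idx is None:
            out[:, j] = means[probe]
            imputed += n
        else:
            col = beta.values[:, col_idx].copy()
            nan = np.isnan(col)
            if nan.any():
                col[nan] = means[probe]
                imputed += int(nan.sum())
            out[:, j] = col
    frac = imputed / float(n * p)
    if frac > max_missing_frac:
        raise ValidationError(
            f"imputed fraction {frac:.3f} exceeds max_missing_frac {max_missing_frac}"
        )
    return out, frac
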