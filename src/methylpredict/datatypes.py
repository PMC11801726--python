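"""Core in-memory containers for methylation data and phenotypes.

Conventions:

* On disk, beta matrices ship probes-as-rows (the series-matrix layout).
* In memory, ``BetaMatrix.values`` is always samples x probes.
* Missing beta values are ``NaN`` -- never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

BETA_BOUND_TOL = 1e-9


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = 1
    if dups:
        raise ValidationError(f"duplicate {what} IDs: {sorted(set(dups))}")


@dataclass
class BetaMatrix:
    """Samples x probes matrix of methylation beta fractions in [0, 1].

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``values``.
    probe_ids : list of str
        Unique probe identifiers, one per column of ``values``.
    values : ndarray of shape (n_samples, n_probes)
        Beta fractions; missing entries are NaN.
    array_label : list of str, optional
        Per-sample array tag (e.g. ``"450K"`` / ``"EPIC"``).
    """

    sample_ids: list[str]
    probe_ids: list[str]
    values: np.ndarray
    array_label: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("beta values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.probe_ids)):
            raise ValidationError(
                f"beta matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.probe_ids)} probes"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.probe_ids, "probe")
        self._check_bounds()
        if self.array_label is not None and len(self.array_label) != len(self.sample_ids):
            raise ValidationError("array_label length does not match sample count")

    def _check_bounds(self) -> None:
        with np.errstate(invalid="ignore"):
            bad = (self.values < -BETA_BOUND_TOL) | (self.values > 1.0 + BETA_BOUND_TOL)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {self.values[i, j]!r} outside [0, 1] at "
                f"probe {self.probe_ids[j]!r}, sample {self.sample_ids[i]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def probe_index(self) -> dict[str, int]:
        return {p: j for j, p in enumerate(self.probe_ids)}

    def subset_samples(self, order: Sequence[int]) -> "BetaMatrix":
        order = list(order)
        return BetaMatrix(
            sample_ids=[self.sample_ids[i] for i in order],
            probe_ids=list(self.probe_ids),
            values=self.values[order, :],
            array_label=None
            if self.array_label is None
            else [self.array_label[i] for i in order],
        )

    def to_frame(self) -> pd.DataFrame:
        """Probes-as-rows frame matching the on-disk layout."""
        return pd.DataFrame(self.values.T, index=self.probe_ids, columns=self.sample_ids)


@dataclass
class PhenotypeTable:
    """Typed phenotype table aligned (or alignable) to a :class:`BetaMatrix`.

    ``data`` holds one row per sample; ``target_col`` names the numeric
    training target (age in years, log-exposure, ...).
    """

    data: pd.DataFrame
    sample_id_col: str = "sample_id"
    target_col: str = "target"
    covariate_cols: list[str] = field(default_factory=list)
    cell_cols: list[str] = field(default_factory=list)
    replicate_col: Optional[str] = None

    def __post_init__(self) -> None:
        for col in [self.sample_id_col, self.target_col]:
            if col not in self.data.columns:
                raise ValidationError(f"phenotype table lacks required column {col!r}")
        self.data = self.data.copy()
        self.data[self.sample_id_col] = self.data[self.sample_id_col].astype(str)
        _check_unique(list(self.data[self.sample_id_col]), "sample")
        self.data[self.target_col] = pd.to_numeric(self.data[self.target_col]).astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data[self.sample_id_col])

    @property
    def target(self) -> np.ndarray:
        return self.data[self.target_col].to_numpy(dtype=float)

    @property
    def replicate_group(self) -> Optional[pd.Series]:
        if self.replicate_col is None:
            return None
        return self.data[self.replicate_col]

    def cell_proportions(self) -> Optional[np.ndarray]:
        if not self.cell_cols:
            return None
        return self.data[self.cell_cols].to_numpy(dtype=float)

    def subset(self, order: Sequence[int]) -> "PhenotypeTable":
        return PhenotypeTable(
            data=self.data.iloc[list(order)].reset_index(drop=True),
            sample_id_col=self.sample_id_col,
            target_col=self.target_col,
            covariate_cols=list(self.covariate_cols),
            cell_cols=list(self.cell_cols),
            replicate_col=self.replicate_col,
        )
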