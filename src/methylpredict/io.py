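"""Readers/writers for beta matrices and phenotype tables, plus sample alignment."""

from __future__ import annotations

import logging
import os
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, PhenotypeTable
from .exceptions import InputError, ValidationError

logger = logging.getLogger(__name__)

CELL_SUM_WARN_TOL = 0.05


def _read_table(path: str, **kwargs) -> pd.DataFrame:
    if not os.path.exists(path):
        raise InputError(f"file not found: {path}")
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        return pd.read_csv(path, sep=sep, float_precision="round_trip", **kwargs)
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise InputError(f"could not parse {path}: {exc}") from exc


def read_beta_matrix(path: str, samples_as_rows: bool = False) -> BetaMatrix:
    """Read a delimited beta matrix.

    Default layout is probes-as-rows: first column holds probe IDs, the
    header row holds sample IDs. Pass ``samples_as_rows=True`` for the
    transposed layout. Non-numeric cells (``NA`` etc.) become NaN; values
    outside [0, 1] by more than 1e-9 raise :class:`ValidationError` naming
    the offending probe and sample.
    """
    df = _read_table(path, index_col=0)
    if samples_as_rows:
        sample_ids = [str(s) for s in df.index]
        probe_ids = [str(p) for p in df.columns]
        values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    else:
        probe_ids = [str(p) for p in df.index]
        sample_ids = [str(s) for s in df.columns]
        values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float).T
    return BetaMatrix(sample_ids=sample_ids, probe_ids=probe_ids, values=values)


def write_beta_matrix(beta: BetaMatrix, path: str) -> None:
    """Write probes-as-rows with full double precision (idempotent re-parse)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = beta.to_frame()
    frame.index.name = "probe_id"
    frame.to_csv(path, sep=sep, float_format="%.17g")


def read_phenotypes(
    path: str,
    target_col: str,
    sample_id_col: str = "sample_id",
    covariate_cols: Optional[Sequence[str]] = None,
    cell_cols: Optional[Sequence[str]] = None,
    replicate_col: Optional[str] = None,
) -> PhenotypeTable:
    """Read a delimited phenotype table with a header row.

    Column roles are given by the caller (typically from the run config).
    If ``cell_cols`` are present, rows whose proportions deviate from 1 by
    more than 0.05 trigger a warning but are kept.
    """
    df = _read_table(path)
    if target_col not in df.columns:
        raise ValidationError(f"phenotype file {path} lacks target column {target_col!r}")
    if sample_id_col not in df.columns:
        raise ValidationError(f"phenotype file {path} lacks sample ID column {sample_id_col!r}")
    covariate_cols = list(covariate_cols or [])
    cell_cols = list(cell_cols or [])
    for col in covariate_cols + cell_cols + ([replicate_col] if replicate_col else []):
        if col not in df.columns:
            raise ValidationError(f"phenotype file {path} lacks column {col!r}")
    table = PhenotypeTable(
        data=df,
        sample_id_col=sample_id_col,
        target_col=target_col,
        covariate_cols=covariate_cols,
        cell_cols=cell_cols,
        replicate_col=replicate_col,
    )
    if cell_cols:
        sums = table.data[cell_cols].sum(axis=1).to_numpy(dtype=float)
        off = np.abs(sums - 1.0) > CELL_SUM_WARN_TOL
        if np.any(off):
            warnings.warn(
                f"{int(off.sum())} sample(s) have cell proportions summing to "
                f"values outside [{1 - CELL_SUM_WARN_TOL}, {1 + CELL_SUM_WARN_TOL}] "
                f"(e.g. {sums[off][0]:.3f}); keeping the data",
                UserWarning,
                stacklevel=2,
            )
    return table


def write_phenotypes(pheno: PhenotypeTable, path: str) -> None:
    pheno.data.to_csv(path, index=False, float_format="%.17g")


def align(beta: BetaMatrix, pheno: PhenotypeTable) -> tuple[BetaMatrix, PhenotypeTable]:
    """Restrict both inputs to their shared samples, in the same order.

    Samples present on only one side are dropped and counted in the log.
    An empty intersection is a hard error.
    """
    beta_pos = {s: i for i, s in enumerate(beta.sample_ids)}
    shared = [s for s in pheno.sample_ids if s in beta_pos]
    if not shared:
        raise ValidationError("no shared sample IDs between beta matrix and phenotypes")
    dropped = (beta.n_samples - len(shared)) + (len(pheno.sample_ids) - len(shared))
    if dropped:
        logger.info("align: dropped %d sample(s) absent from one side", dropped)
    pheno_pos = {s: i for i, s in enumerate(pheno.sample_ids)}
    beta_out = beta.subset_samples([beta_pos[s] for s in shared])
    pheno_out = pheno.subset([pheno_pos[s] for s in shared])
    return beta_out, pheno_out
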