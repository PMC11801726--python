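"""Seeded generator of synthetic methylation studies with known ground truth.

Signal is injected on the latent logit scale and mapped through the
inverse logit, so beta values stay strictly inside (0, 1) with no clipping
artifacts. Replicate pairs share one latent truth and differ only by
independent technical noise plus, for the "second array" member,
probe-specific additive latent offsets on a configurable probe subset.
All randomness flows from ``numpy.random.default_rng(cfg.seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, PhenotypeTable
from .exceptions import ValidationError

CELL_TYPES = ("CD8T", "CD4T", "NK", "Gran", "Mono", "Bcell")


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of one simulated methylation study."""

    n_samples: int = 100
    n_probes: int = 1000
    n_signal_probes: int = 20
    #: signal probes come in blocks sharing one latent effect (block-diagonal
    #: latent correlation); 1 = independent signal probes
    signal_block_size: int = 1
    effect_model: str = "linear_age"  # linear_age | log_age | nonlinear_exposure
    effect_size_range: tuple[float, float] = (0.05, 0.15)
    noise_sd: float = 0.2
    baseline_sd: float = 1.5
    n_replicate_pairs: int = 0
    array_offset_frac: float = 0.0
    array_offset_sd: float = 0.0
    age_range: tuple[float, float] = (0.0, 21.0)
    exposure_mean: float = 0.0
    exposure_sd: float = 1.0
    cell_profile: Optional[tuple[float, ...]] = None  # Dirichlet alphas, 6 cell types
    cell_effect_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_probes > self.n_probes:
            raise ValidationError("n_signal_probes exceeds n_probes")
        if self.noise_sd < 0 or self.array_offset_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if not 0.0 <= self.array_offset_frac <= 1.0:
            raise ValidationError("array_offset_frac must be in [0, 1]")
        if self.effect_model not in ("linear_age", "log_age", "nonlinear_exposure"):
            raise ValidationError(f"unknown effect model {self.effect_model!r}")
        if self.n_replicate_pairs > self.n_samples:
            raise ValidationError("more replicate pairs than samples")
        if self.cell_profile is not None and len(self.cell_profile) != len(CELL_TYPES):
            raise ValidationError(f"cell_profile needs {len(CELL_TYPES)} alphas")
        if self.signal_block_size < 1:
            raise ValidationError("signal_block_size must be >= 1")
        if self.n_signal_probes % self.signal_block_size:
            raise ValidationError("n_signal_probes must be a multiple of signal_block_size")


def _effect_shape(target: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    if cfg.effect_model == "linear_age":
        return target
    if cfg.effect_model == "log_age":
        return np.log(target + 1.0) - np.log(22.0)
    z = (target - cfg.exposure_mean) / cfg.exposure_sd
    return z / np.sqrt(1.0 + z**2)  # saturating


def generate_study(
    cfg: SyntheticConfig,
) -> tuple[BetaMatrix, PhenotypeTable, dict]:
    """Simulate one study; returns (beta, phenotypes, truth).

    ``truth`` records signal probe IDs, their latent-scale slopes, and the
    array-offset probes/values so recovery can be scored exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_probes
    probe_ids = [f"cg{j:07d}" for j in range(p)]
    sample_ids = [f"S{i:05d}" for i in range(n)]

    if cfg.effect_model in ("linear_age", "log_age"):
        target = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    else:
        target = rng.normal(cfg.exposure_mean, cfg.exposure_sd, size=n)

    baseline = rng.normal(0.0, cfg.baseline_sd, size=p)
    signal_idx = np.sort(rng.choice(p, size=cfg.n_signal_probes, replace=False))
    n_blocks = cfg.n_signal_probes // cfg.signal_block_size
    block_mag = rng.uniform(*cfg.effect_size_range, size=n_blocks)
    block_sign = rng.choice([-1.0, 1.0], size=n_blocks)
    # probes within a block share one latent effect (correlated signal)
    effects = np.repeat(block_mag * block_sign, cfg.signal_block_size)

    f = _effect_shape(target, cfg)
    latent = np.tile(baseline, (n, 1))
    latent[:, signal_idx] += np.outer(f, effects)
    if cfg.effect_model == "nonlinear_exposure" and cfg.n_signal_probes >= 2:
        # the first signal pair carries an extra non-monotone interaction shape
        z = (target - cfg.exposure_mean) / cfg.exposure_sd
        latent[:, signal_idx[:2]] += np.outer(z * f, effects[:2])

    cell_props = None
    if cfg.cell_profile is not None:
        cell_props = rng.dirichlet(np.asarray(cfg.cell_profile, dtype=float), size=n)
        n_cell_probes = max(1, p // 10)
        for c in range(len(CELL_TYPES)):
            probes_c = rng.choice(p, size=n_cell_probes, replace=False)
            loading = rng.normal(0.0, cfg.cell_effect_sd, size=n_cell_probes)
            centered = cell_props[:, c] - cell_props[:, c].mean()
            latent[:, probes_c] += np.outer(centered, loading)

    n_offset = int(round(cfg.array_offset_frac * p))
    offset_idx = np.sort(rng.choice(p, size=n_offset, replace=False)) if n_offset else np.array([], dtype=int)
    offsets = rng.normal(0.0, cfg.array_offset_sd, size=n_offset)

    values = _expit(latent + rng.normal(0.0, cfg.noise_sd, size=(n, p)))
    array_label = ["A1"] * n

    rows = {
        "sample_id": list(sample_ids),
        "target": list(target),
        "array": list(array_label),
        "replicate_group": [""] * n,
    }
    if cell_props is not None:
        for c, name in enumerate(CELL_TYPES):
            rows[f"cell_{name}"] = list(cell_props[:, c])

    # replicate pairs: re-measure the first k samples on a second array
    if cfg.n_replicate_pairs:
        k = cfg.n_replicate_pairs
        rep_latent = latent[:k].copy()
        rep_latent[:, offset_idx] += offsets[None, :]
        rep_values = _expit(rep_latent + rng.normal(0.0, cfg.noise_sd, size=(k, p)))
        values = np.vstack([values, rep_values])
        for i in range(k):
            rows["sample_id"].append(f"{sample_ids[i]}_rep2")
            rows["target"].append(target[i])
            rows["array"].append("A2")
            rows["replicate_group"][i] = sample_ids[i]
            rows["replicate_group"].append(sample_ids[i])
            if cell_props is not None:
                for c, name in enumerate(CELL_TYPES):
                    rows[f"cell_{name}"].append(cell_props[i, c])
        sample_ids = rows["sample_id"]
        array_label = rows["array"]

    beta = BetaMatrix(
        sample_ids=list(sample_ids),
        probe_ids=probe_ids,
        values=values,
        array_label=list(array_label),
    )
    pheno = PhenotypeTable(
        data=pd.DataFrame(rows),
        sample_id_col="sample_id",
        target_col="target",
        cell_cols=[f"cell_{c}" for c in CELL_TYPES] if cell_props is not None else [],
        replicate_col="replicate_group",
    )
    truth = {
        "signal_probes": [probe_ids[j] for j in signal_idx],
        "effects": {probe_ids[j]: float(e) for j, e in zip(signal_idx, effects)},
        "offset_probes": [probe_ids[j] for j in offset_idx],
        "offsets": {probe_ids[j]: float(o) for j, o in zip(offset_idx, offsets)},
        "effect_model": cfg.effect_model,
    }
    return beta, pheno, truth


def generate_null_study(cfg: SyntheticConfig) -> tuple[BetaMatrix, PhenotypeTable]:
    """Same generative process with zero signal probes (target independent)."""
    beta, pheno, _ = generate_study(replace(cfg, n_signal_probes=0))
    return beta, pheno
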