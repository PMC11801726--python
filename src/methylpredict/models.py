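"""Serializable predictor models and their on-disk directory format.

A saved model is a directory holding ``manifest.json`` (model kind, target
transform, hyperparameters, probe list, meta-weights) plus flat delimited
numeric arrays (``center.tsv``, ``rotation.tsv``, ``coefficients.tsv``).
Everything is plain text with full double precision, so a load/save round
trip reproduces predictions bit-for-bit.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .exceptions import InputError, ValidationError
from .superlearner import LearnerSpec
from .transforms import AgeTransform

_FLOAT_FMT = "%.17g"


@dataclass
class CpGModel:
    """Sparse linear predictor over individual probes."""

    intercept: float
    coefficients: dict[str, float]
    training_probe_means: dict[str, float]
    target_transform: AgeTransform

    def __post_init__(self) -> None:
        missing = [p for p in self.coefficients if p not in self.training_probe_means]
        if missing:
            raise ValidationError(
                f"coefficient probes lack training means: {missing[:3]}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.coefficients)

    def linear_predict(self, X: np.ndarray) -> np.ndarray:
        """X in probe order -> prediction on the transformed target scale."""
        coef = np.array([self.coefficients[p] for p in self.probe_ids])
        return self.intercept + np.asarray(X, dtype=float) @ coef


@dataclass
class PCAModel:
    """Sparse linear predictor over training-centered principal components."""

    probe_ids: list[str]
    center: np.ndarray
    rotation: np.ndarray
    retained_pc_count: int
    pc_intercept: float
    pc_coefficients: dict[int, float]
    target_transform: AgeTransform

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if self.rotation.shape != (len(self.probe_ids), self.retained_pc_count):
            raise ValidationError(
                f"rotation shape {self.rotation.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {self.retained_pc_count} PCs"
            )

    @property
    def training_probe_means(self) -> dict[str, float]:
        return dict(zip(self.probe_ids, self.center.tolist()))

    def linear_predict(self, scores: np.ndarray) -> np.ndarray:
        """Scores (samples x retained PCs) -> transformed-scale prediction."""
        coef = np.zeros(self.retained_pc_count)
        for k, v in self.pc_coefficients.items():
            coef[int(k)] = v
        return self.pc_intercept + np.asarray(scores, dtype=float) @ coef


@dataclass
class SLModel:
    """Stacked ensemble over the full principal-component score matrix."""

    probe_ids: list[str]
    center: np.ndarray
    rotation: np.ndarray
    fitted_learners: list[tuple[LearnerSpec, dict]]
    meta_weights: np.ndarray
    cv_config: dict = field(default_factory=dict)
    target_transform: AgeTransform = field(default_factory=AgeTransform)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.meta_weights = np.asarray(self.meta_weights, dtype=float)
        if len(self.meta_weights) != len(self.fitted_learners):
            raise ValidationError("meta_weights length != fitted learner count")
        if np.any(self.meta_weights < -1e-12) or abs(self.meta_weights.sum() - 1.0) > 1e-12:
            raise ValidationError("meta_weights must lie on the simplex")

    @property
    def training_probe_means(self) -> dict[str, float]:
        return dict(zip(self.probe_ids, self.center.tolist()))


Model = Union[CpGModel, PCAModel, SLModel]


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def save_model(model: Model, path: str) -> None:
    """Write a model directory: manifest.json + delimited numeric arrays."""
    os.makedirs(path, exist_ok=True)
    manifest: dict = {"format_version": 1, "transform": model.target_transform.to_dict()}
    if isinstance(model, CpGModel):
        manifest["kind"] = "cpg"
        manifest["intercept"] = float(model.intercept)
        manifest["probe_ids"] = model.probe_ids
        with open(os.path.join(path, "coefficients.tsv"), "w") as fh:
            fh.write("probe_id\tcoefficient\ttraining_mean\n")
            for p in model.probe_ids:
                fh.write(
                    f"{p}\t{model.coefficients[p]:.17g}\t{model.training_probe_means[p]:.17g}\n"
                )
    elif isinstance(model, PCAModel):
        manifest["kind"] = "pca"
        manifest["probe_ids"] = model.probe_ids
        manifest["retained_pc_count"] = model.retained_pc_count
        manifest["pc_intercept"] = float(model.pc_intercept)
        np.savetxt(os.path.join(path, "center.tsv"), model.center, fmt=_FLOAT_FMT)
        np.savetxt(os.path.join(path, "rotation.tsv"), model.rotation, fmt=_FLOAT_FMT, delimiter="\t")
        with open(os.path.join(path, "coefficients.tsv"), "w") as fh:
            fh.write("pc_index\tcoefficient\n")
            for k in sorted(model.pc_coefficients):
                fh.write(f"{k}\t{model.pc_coefficients[k]:.17g}\n")
    elif isinstance(model, SLModel):
        manifest["kind"] = "slpca"
        manifest["probe_ids"] = model.probe_ids
        manifest["meta_weights"] = model.meta_weights.tolist()
        manifest["cv_config"] = model.cv_config
        manifest["n_components"] = int(model.rotation.shape[1])
        manifest["learners"] = [
            {"spec": spec.to_dict(), "params": _jsonify(params)}
            for spec, params in model.fitted_learners
        ]
        np.savetxt(os.path.join(path, "center.tsv"), model.center, fmt=_FLOAT_FMT)
        np.savetxt(os.path.join(path, "rotation.tsv"), model.rotation, fmt=_FLOAT_FMT, delimiter="\t")
    else:
        raise ValidationError(f"unknown model type {type(model).__name__}")
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")


def _load_matrix(path: str, ncols_expected: int | None = None) -> np.ndarray:
    arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    if ncols_expected is not None and arr.shape[1] != ncols_expected:
        raise InputError(
            f"{path}: expected {ncols_expected} columns, found {arr.shape[1]}"
        )
    return arr


def _numify(params: dict) -> dict:
    out = {}
    for k, v in params.items():
        if isinstance(v, list):
            out[k] = np.asarray(v, dtype=float) if k != "feature_idx" else list(v)
        else:
            out[k] = v
    return out


def load_model(path: str) -> Model:
    """Load a model directory; manifest/array shape mismatches are hard errors."""
    manifest_path = os.path.join(path, "manifest.json")
    if not os.path.exists(manifest_path):
        raise InputError(f"no manifest.json under {path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    transform = AgeTransform.from_dict(manifest["transform"])
    kind = manifest.get("kind")
    if kind == "cpg":
        coeffs: dict[str, float] = {}
        means: dict[str, float] = {}
        with open(os.path.join(path, "coefficients.tsv")) as fh:
            next(fh)
            for line in fh:
                p, c, m = line.rstrip("\n").split("\t")
                coeffs[p] = float(c)
                means[p] = float(m)
        if list(coeffs) != list(manifest["probe_ids"]):
            raise InputError(f"{path}: coefficient probes disagree with manifest")
        return CpGModel(
            intercept=float(manifest["intercept"]),
            coefficients=coeffs,
            training_probe_means=means,
            target_transform=transform,
        )
    if kind == "pca":
        probe_ids = list(manifest["probe_ids"])
        q = int(manifest["retained_pc_count"])
        center = _load_matrix(os.path.join(path, "center.tsv")).ravel()
        rotation = _load_matrix(os.path.join(path, "rotation.tsv"), ncols_expected=q)
        if len(center) != len(probe_ids) or rotation.shape[0] != len(probe_ids):
            raise InputError(f"{path}: center/rotation rows disagree with probe list")
        pc_coeffs: dict[int, float] = {}
        with open(os.path.join(path, "coefficients.tsv")) as fh:
            next(fh)
            for line in fh:
                k, c = line.rstrip("\n").split("\t")
                pc_coeffs[int(k)] = float(c)
        return PCAModel(
            probe_ids=probe_ids,
            center=center,
            rotation=rotation,
            retained_pc_count=q,
            pc_intercept=float(manifest["pc_intercept"]),
            pc_coefficients=pc_coeffs,
            target_transform=transform,
        )
    if kind == "slpca":
        probe_ids = list(manifest["probe_ids"])
        q = int(manifest["n_components"])
        center = _load_matrix(os.path.join(path, "center.tsv")).ravel()
        rotation = _load_matrix(os.path.join(path, "rotation.tsv"), ncols_expected=q)
        if len(center) != len(probe_ids) or rotation.shape[0] != len(probe_ids):
            raise InputError(f"{path}: center/rotation rows disagree with probe list")
        learners = [
            (LearnerSpec.from_dict(entry["spec"]), _numify(entry["params"]))
            for entry in manifest["learners"]
        ]
        return SLModel(
            probe_ids=probe_ids,
            center=center,
            rotation=rotation,
            fitted_learners=learners,
            meta_weights=np.asarray(manifest["meta_weights"], dtype=float),
            cv_config=manifest.get("cv_config", {}),
            target_transform=transform,
        )
    raise InputError(f"unknown model kind {kind!r} in {manifest_path}")
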