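"""Supervised leaf/stem segmentation with multi-scale eigen-features (LFPC-s).

Per-point feature vectors are the four covariance-eigenvalue ratios F1..F4
concatenated over six neighbourhood radii (2–7 mm, 24 features), classified
by a two-class linear SVM.  The training protocol is train-on-one-model:
fit on a single labeled plant, predict on the rest.

No spatial regularisation is applied to the predictions — isolated label
flips along stems and on leaves are an expected failure mode of this method
and are deliberately left visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .core import LabeledPointCloud, OrganLabel
from .errors import ValidationError
from .features import DEFAULT_RADII, MultiscaleFeatureTable, multiscale_features

__all__ = ["SvmConfig", "SvmModel", "train_svm", "predict_svm", "segment_lfpc_s"]

_FORMAT_VERSION = 1


@dataclass
class SvmConfig:
    """Training configuration for the linear SVM classifier.

    ``standardize`` (on by default) z-scores each feature column from the
    training data — the eigenvalue ratios have heterogeneous ranges and the
    linear SVM is scale-sensitive.  ``class_weight="balanced"`` enables
    inverse-frequency class weighting; ``subsample`` draws a balanced random
    subset of at most that many points per class before fitting.
    """

    radii: tuple[float, ...] = DEFAULT_RADII
    C: float = 1.0
    standardize: bool = True
    class_weight: Optional[str] = None
    subsample: Optional[int] = None
    seed: int = 0


@dataclass
class SvmModel:
    """A fitted linear SVM with its feature schema and training metadata."""

    pipeline: Pipeline
    radii: tuple[float, ...]
    n_features: int
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": _FORMAT_VERSION,
                "pipeline": self.pipeline,
                "radii": self.radii,
                "n_features": self.n_features,
                "metadata": self.metadata,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SvmModel":
        payload = joblib.load(path)
        if payload.get("format_version") != _FORMAT_VERSION:
            raise ValidationError(
                f"unsupported model format version {payload.get('format_version')!r}"
            )
        return cls(
            pipeline=payload["pipeline"],
            radii=tuple(payload["radii"]),
            n_features=int(payload["n_features"]),
            metadata=payload["metadata"],
        )


def train_svm(
    feature_table: MultiscaleFeatureTable,
    labels: np.ndarray,
    config: SvmConfig | None = None,
) -> SvmModel:
    """Fit the two-class linear SVM on a labeled feature table.

    ``labels`` are organ codes and must contain both leaf and stem.
    Deterministic for a fixed config seed and input order.
    """
    config = config or SvmConfig()
    X = feature_table.matrix
    y = np.asarray(labels, dtype=np.int64)
    if len(y) != len(X):
        raise ValidationError(f"{len(y)} labels for {len(X)} feature rows")
    if not np.isfinite(X).all():
        raise ValidationError("feature table contains non-finite values")
    classes = np.unique(y)
    if not np.array_equal(classes, [int(OrganLabel.STEM), int(OrganLabel.LEAF)]):
        raise ValidationError(
            f"training labels must contain exactly leaf and stem, got codes {classes.tolist()}"
        )
    if config.subsample is not None:
        rng = np.random.default_rng(config.seed)
        keep = []
        for c in classes:
            members = np.flatnonzero(y == c)
            if len(members) > config.subsample:
                members = rng.choice(members, size=config.subsample, replace=False)
            keep.append(members)
        keep = np.sort(np.concatenate(keep))
        X, y = X[keep], y[keep]
    steps = []
    if config.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(
        (
            "svm",
            LinearSVC(
                C=config.C,
                class_weight=config.class_weight,
                dual=False,
                random_state=config.seed,
            ),
        )
    )
    pipeline = Pipeline(steps)
    pipeline.fit(X, y)
    return SvmModel(
        pipeline=pipeline,
        radii=tuple(feature_table.radii),
        n_features=X.shape[1],
        metadata={"n_train": int(len(y)), "seed": config.seed, "C": config.C},
    )


def predict_svm(model: SvmModel, feature_table: MultiscaleFeatureTable) -> np.ndarray:
    """Per-point organ codes (leaf/stem) for a feature table. Deterministic."""
    X = feature_table.matrix
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"feature table has {X.shape[1]} columns, model expects {model.n_features}"
        )
    if len(X) == 0:
        return np.empty(0, dtype=np.int64)
    return model.pipeline.predict(X).astype(np.int64)


def segment_lfpc_s(
    model: SvmModel, cloud: LabeledPointCloud, radii: Sequence[float] | None = None
) -> np.ndarray:
    """Extract multi-scale features of a cloud and classify them."""
    table = multiscale_features(cloud, radii or model.radii)
    return predict_svm(model, table)
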