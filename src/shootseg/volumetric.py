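"""Volumetric leaf/stem segmentation: filter-bank features + random forest (LFVD).

Input is the *binary* surface-voxel volume of the plant shoot (interior
voxels zeroed), so the classifier sees geometry only, no X-ray intensity.
Per Gaussian scale ``s`` (mm) the bank computes 22 channels:

=====================  =====
smoothed intensity     1
gradient magnitude     1
Laplacian of Gaussian  1
difference of Gauss.   1   (smooth(s) − smooth(1.6·s))
structure-tensor eigs  3   (ascending)
Hessian eigenvalues    3   (ascending)
structure-tensor raw   6   (xx, xy, xz, yy, yz, zz)
Hessian raw            6
=====================  =====

Default scales are 0.7, 1.0, 1.6, 3.5, 5.0 and 10.0 mm (132 features).
Anisotropic spacing is handled by per-axis sigma ``s / spacing(axis)`` in
voxel units; derivatives are expressed per millimetre.  The structure tensor
is the Gaussian-smoothed outer product of first derivatives with inner and
outer scale both ``s``.  All filters use replicate ("nearest") boundary
handling, which only affects a thin shell near the grid border.

A random forest is trained on leaf/stem voxels of one labeled model and
predicts organ codes on the surface voxels of unseen models.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .core import OrganLabel, VoxelGrid
from .errors import ValidationError

__all__ = [
    "DEFAULT_SCALES",
    "VoxelFeatureBank",
    "RfConfig",
    "RfModel",
    "compute_feature_bank",
    "train_rf",
    "predict_volume",
]

#: Gaussian scales (mm) of the filter bank.
DEFAULT_SCALES = (0.7, 1.0, 1.6, 3.5, 5.0, 10.0)

#: Ratio of the two sigmas in the difference-of-Gaussians channel.
DOG_RATIO = 1.6

_BOUNDARY_MODE = "nearest"
_TRUNCATE = 4.0

_TENSOR_PAIRS = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def _gaussian_kernel1d(sigma: float, order: int, truncate: float = _TRUNCATE) -> np.ndarray:
    """Sampled Gaussian (derivative) kernel, DC-corrected for ``order >= 1``.

    The polynomial-times-Gaussian construction matches the usual sampled
    derivative-of-Gaussian; truncation leaves even-order kernels with a small
    nonzero sum, which is removed so that derivatives of a constant field are
    exactly zero.
    """
    radius = max(int(truncate * sigma + 0.5), 1)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    phi = np.exp(-0.5 * (x / sigma) ** 2)
    phi /= phi.sum()
    if order == 0:
        return phi
    # q(x) with (q * phi)' = (q' - x/sigma^2 q) * phi, iterated `order` times
    exponents = np.arange(order + 1)
    q = np.zeros(order + 1)
    q[0] = 1.0
    deriv = np.diag(exponents[1:], 1) - np.diag(np.ones(order) / sigma**2, -1)
    for _ in range(order):
        q = deriv.dot(q)
    kernel = (x[:, None] ** exponents).dot(q) * phi
    kernel -= kernel.sum() / len(kernel)
    return kernel


def channel_names(scales: Sequence[float] = DEFAULT_SCALES) -> list[str]:
    """Flat channel names, 22 per scale, scales in the given order."""
    names = []
    base = (
        ["gauss", "grad_mag", "log", "dog"]
        + [f"st_eig{k}" for k in (1, 2, 3)]
        + [f"hess_eig{k}" for k in (1, 2, 3)]
        + [f"st_{a}{b}" for a, b in (("x", "x"), ("x", "y"), ("x", "z"), ("y", "y"), ("y", "z"), ("z", "z"))]
        + [f"hess_{a}{b}" for a, b in (("x", "x"), ("x", "y"), ("x", "z"), ("y", "y"), ("y", "z"), ("z", "z"))]
    )
    for s in scales:
        names += [f"{n}_s{s:g}" for n in base]
    return names


@dataclass
class VoxelFeatureBank:
    """Per-voxel filter-bank responses at the masked voxel positions."""

    scales: tuple[float, ...]
    mask_indices: np.ndarray  # (M, 3) voxel indices the rows correspond to
    features: np.ndarray  # (M, 22 * n_scales)
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    @property
    def column_names(self) -> list[str]:
        return channel_names(self.scales)

    def schema_hash(self) -> str:
        key = f"{self.scales}|22|{self.spacing}"
        return hashlib.sha256(key.encode()).hexdigest()[:16]


def _sorted_eigs(entries: list[np.ndarray]) -> np.ndarray:
    """Ascending eigenvalues of symmetric 3x3 matrices given 6 unique entries."""
    m = len(entries[0])
    mat = np.empty((m, 3, 3))
    for (a, b), vals in zip(_TENSOR_PAIRS, entries):
        mat[:, a, b] = vals
        mat[:, b, a] = vals
    return np.linalg.eigvalsh(mat)


def compute_feature_bank(
    grid: VoxelGrid,
    scales: Sequence[float] = DEFAULT_SCALES,
    mask: Optional[np.ndarray] = None,
) -> VoxelFeatureBank:
    """Filter-bank features of a binary surface volume at the masked voxels.

    ``mask`` defaults to the nonzero voxels of the grid itself.  Responses
    are computed on the full grid by separable Gaussian-derivative filtering
    and sampled at the mask.
    """
    if grid.kind != "binary_mask":
        raise ValidationError(f"feature bank expects a binary_mask grid, got {grid.kind!r}")
    scales = tuple(float(s) for s in scales)
    if any(s <= 0 for s in scales):
        raise ValidationError("scales must be positive")
    vol = grid.values.astype(np.float32)
    spacing = np.asarray(grid.spacing)
    if mask is None:
        mask = grid.values != 0
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vol.shape:
            raise ValidationError("mask shape does not match grid")
    midx = np.argwhere(mask)
    mflat = (midx[:, 0], midx[:, 1], midx[:, 2])

    def gauss(data, sigma_mm, order=(0, 0, 0)):
        out = data
        for ax, o in enumerate(order):
            kernel = _gaussian_kernel1d(sigma_mm / spacing[ax], o)
            out = ndimage.correlate1d(out, kernel[::-1], axis=ax, mode=_BOUNDARY_MODE)
            if o:  # derivatives w.r.t. physical mm, not voxel index
                out = out / spacing[ax] ** o
        return out

    blocks = []
    for s in scales:
        cols: list[np.ndarray] = []
        smoothed = gauss(vol, s)
        cols.append(smoothed[mflat])

        deriv1 = [gauss(vol, s, order=tuple(1 if a == ax else 0 for a in range(3))) for ax in range(3)]
        grad_mag = np.sqrt(deriv1[0] ** 2 + deriv1[1] ** 2 + deriv1[2] ** 2)
        cols.append(grad_mag[mflat])

        hess = {}
        for a, b in _TENSOR_PAIRS:
            order = [0, 0, 0]
            order[a] += 1
            order[b] += 1
            hess[(a, b)] = gauss(vol, s, order=tuple(order))
        log_resp = hess[(0, 0)] + hess[(1, 1)] + hess[(2, 2)]
        cols.append(log_resp[mflat])

        dog = smoothed - gauss(vol, DOG_RATIO * s)
        cols.append(dog[mflat])

        st = [gauss(deriv1[a] * deriv1[b], s)[mflat] for a, b in _TENSOR_PAIRS]
        hess_m = [hess[(a, b)][mflat] for a, b in _TENSOR_PAIRS]
        st_eigs = _sorted_eigs(st)
        hess_eigs = _sorted_eigs(hess_m)
        cols += [st_eigs[:, k] for k in range(3)]
        cols += [hess_eigs[:, k] for k in range(3)]
        cols += st
        cols += hess_m
        blocks.append(np.column_stack(cols))

    features = np.hstack(blocks).astype(np.float64)
    if not np.isfinite(features).all():
        raise ValidationError("filter bank produced non-finite responses")
    return VoxelFeatureBank(
        scales=scales,
        mask_indices=midx,
        features=features,
        shape=vol.shape,
        spacing=grid.spacing,
    )


@dataclass
class RfConfig:
    """Random-forest hyperparameters: 100 trees, unlimited depth,
    sqrt(n_features) per split, single-threaded for reproducibility."""

    n_trees: int = 100
    max_depth: Optional[int] = None
    seed: int = 0


@dataclass
class RfModel:
    """A fitted voxel-classification forest with its feature schema."""

    forest: RandomForestClassifier
    scales: tuple[float, ...]
    schema_hash: str
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": 1,
                "forest": self.forest,
                "scales": self.scales,
                "schema_hash": self.schema_hash,
                "metadata": self.metadata,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "RfModel":
        payload = joblib.load(path)
        if payload.get("format_version") != 1:
            raise ValidationError("unsupported model format version")
        return cls(
            forest=payload["forest"],
            scales=tuple(payload["scales"]),
            schema_hash=payload["schema_hash"],
            metadata=payload["metadata"],
        )


def train_rf(
    bank: VoxelFeatureBank,
    label_grid: VoxelGrid,
    config: RfConfig | None = None,
) -> RfModel:
    """Train the forest on the leaf/stem voxels of a labeled volume.

    Voxels whose ground truth is not leaf or stem (flower, pot, tag,
    background) are excluded from training.
    """
    config = config or RfConfig()
    if label_grid.kind != "label":
        raise ValidationError("train_rf needs a label grid")
    if label_grid.shape != bank.shape:
        raise ValidationError("label grid shape does not match feature bank")
    idx = bank.mask_indices
    y = label_grid.values[idx[:, 0], idx[:, 1], idx[:, 2]].astype(np.int64)
    keep = np.isin(y, [int(OrganLabel.STEM), int(OrganLabel.LEAF)])
    X, y = bank.features[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise ValidationError("training voxels contain a single class; need leaf and stem")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features="sqrt",
        random_state=config.seed,
        n_jobs=1,
        oob_score=True,
    )
    forest.fit(X, y)
    return RfModel(
        forest=forest,
        scales=bank.scales,
        schema_hash=bank.schema_hash(),
        metadata={
            "n_train": int(len(y)),
            "seed": config.seed,
            "oob_score": float(forest.oob_score_),
        },
    )


def predict_volume(model: RfModel, bank: VoxelFeatureBank) -> VoxelGrid:
    """Organ labels (leaf/stem) at the bank's masked voxels; background elsewhere."""
    if bank.schema_hash() != model.schema_hash:
        raise ValidationError("feature bank schema does not match the trained model")
    out = np.zeros(bank.shape, dtype=np.uint8)
    if len(bank.mask_indices):
        pred = model.forest.predict(bank.features).astype(np.uint8)
        idx = bank.mask_indices
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = pred
    return VoxelGrid(out, bank.spacing, kind="label")
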