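"""Core domain types for 3D plant shoot models.

Two in-memory containers are used throughout the package:

* :class:`LabeledPointCloud` — ``N x 3`` point coordinates in millimetres with
  optional per-point organ labels.  All point-based methods consume this.
* :class:`VoxelGrid` — a dense 3D array with per-axis spacing in millimetres,
  holding intensities, organ labels, or a binary mask.  Volumetric methods
  consume this.

The organ-label convention follows the common release convention for annotated
X-ray CT rosebush models: ``0`` background, ``1`` stem (main branches *and*
petioles share this code), ``2`` leaf, ``3`` flower, ``4`` pot, ``5`` tag.
The *shoot* is the union of stem, leaf and flower.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import ValidationError

__all__ = [
    "OrganLabel",
    "SHOOT_CLASSES",
    "LabeledPointCloud",
    "VoxelGrid",
    "ManifestEntry",
    "DatasetManifest",
    "shoot_mask",
    "extract_surface",
    "voxels_to_points",
]


class OrganLabel(enum.IntEnum):
    """Organ class codes used in label grids and labeled point clouds."""

    BACKGROUND = 0
    STEM = 1  # includes petioles: same geometry, spatially connected
    LEAF = 2
    FLOWER = 3
    POT = 4
    TAG = 5


#: Classes that make up the plant shoot (above-soil plant material).
SHOOT_CLASSES = frozenset({OrganLabel.STEM, OrganLabel.LEAF, OrganLabel.FLOWER})

_VALID_CODES = frozenset(int(l) for l in OrganLabel)

ValueKind = Literal["intensity", "label", "binary_mask"]


def _validate_labels(labels: np.ndarray, context: str) -> None:
    bad = np.setdiff1d(np.unique(labels), sorted(_VALID_CODES))
    if bad.size:
        raise ValidationError(
            f"{context}: unknown organ label code(s) {bad.tolist()}; valid codes are 0..5"
        )


@dataclass
class LabeledPointCloud:
    """Points on the surface of a plant shoot, in physical mm coordinates.

    Parameters
    ----------
    coords:
        ``(N, 3)`` float array, millimetres.
    labels:
        Optional ``(N,)`` integer array of :class:`OrganLabel` codes.
    """

    coords: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError(
                f"coords must have shape (N, 3), got {self.coords.shape}"
            )
        if not np.isfinite(self.coords).all():
            raise ValidationError("coords contain non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self.coords),):
                raise ValidationError(
                    f"labels length {self.labels.shape} does not match N={len(self.coords)}"
                )
            _validate_labels(self.labels, "point cloud labels")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def has_labels(self) -> bool:
        return self.labels is not None

    def transformed(self, rotation: np.ndarray, translation: Sequence[float]) -> "LabeledPointCloud":
        """Return a rigidly moved copy (labels shared, coordinates new)."""
        rotation = np.asarray(rotation, dtype=np.float64)
        translation = np.asarray(translation, dtype=np.float64)
        return LabeledPointCloud(self.coords @ rotation.T + translation, self.labels)


@dataclass
class VoxelGrid:
    """Dense voxel volume with physical spacing.

    ``values`` is indexed ``[x, y, z]`` where ``z`` is the slice axis; spacing
    gives mm per voxel along each axis (anisotropic spacing allowed, e.g. the
    0.9766/0.9766/0.5 mm regime of raw CT stacks).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    kind: ValueKind = "intensity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive reals, got {self.spacing}")
        if self.kind not in ("intensity", "label", "binary_mask"):
            raise ValidationError(f"unknown value_kind {self.kind!r}")
        if self.kind == "label":
            _validate_labels(self.values, "label grid")
        elif self.kind == "binary_mask":
            vals = np.unique(self.values)
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError(
                    f"binary_mask grid contains values other than 0/1: {vals[:10].tolist()}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class ManifestEntry:
    model_id: str
    cloud_path: Path
    volume_path: Path
    role: Literal["train", "test"]


@dataclass
class DatasetManifest:
    """A train/test split over a set of plant models on disk."""

    entries: list[ManifestEntry] = field(default_factory=list)

    @property
    def train(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.role == "train"]

    @property
    def test(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.role == "test"]

    def validate(self, require_train: bool = False) -> None:
        for e in self.entries:
            for p in (e.cloud_path, e.volume_path):
                if not Path(p).exists():
                    raise ValidationError(f"manifest entry {e.model_id}: missing file {p}")
        if require_train and not self.train:
            raise ValidationError("manifest has no train entry")


# ---------------------------------------------------------------------------
# grid operations


def shoot_mask(grid: VoxelGrid) -> VoxelGrid:
    """Binary mask of the plant shoot (stem + leaf + flower voxels)."""
    if grid.kind != "label":
        raise ValidationError(f"shoot_mask expects a label grid, got {grid.kind!r}")
    mask = np.isin(grid.values, [int(c) for c in sorted(SHOOT_CLASSES)])
    return VoxelGrid(mask.astype(np.uint8), grid.spacing, kind="binary_mask")


def extract_surface(grid: VoxelGrid, connectivity: int = 26) -> VoxelGrid:
    """Keep only surface voxels of a binary volume.

    A foreground voxel is on the surface iff at least one of its neighbours
    (26- or 6-neighbourhood; out-of-bounds counts as background) is background.
    Interior voxels are zeroed.  Idempotent.
    """
    if grid.kind != "binary_mask":
        raise ValidationError(f"extract_surface expects a binary_mask grid, got {grid.kind!r}")
    if connectivity not in (6, 26):
        raise ValidationError("connectivity must be 6 or 26")
    fg = grid.values.astype(bool)
    structure = ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)
    # border_value=0: voxels touching the grid boundary have background neighbours
    interior = ndimage.binary_erosion(fg, structure=structure, border_value=0)
    surface = fg & ~interior
    return VoxelGrid(surface.astype(np.uint8), grid.spacing, kind="binary_mask")


def voxels_to_points(grid: VoxelGrid) -> LabeledPointCloud:
    """One point per nonzero voxel, at the voxel centre in physical mm.

    The centre of voxel index ``(i, j, k)`` is ``(index + 0.5) * spacing`` per
    axis.  For label grids the voxel labels are carried over; for binary masks
    the cloud is unlabeled.
    """
    if grid.kind not in ("label", "binary_mask"):
        raise ValidationError("voxels_to_points expects a label or binary_mask grid")
    idx = np.argwhere(grid.values != 0)
    coords = (idx + 0.5) * np.asarray(grid.spacing)
    labels = None
    if grid.kind == "label":
        labels = grid.values[idx[:, 0], idx[:, 1], idx[:, 2]].astype(np.int64)
    return LabeledPointCloud(coords, labels)
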