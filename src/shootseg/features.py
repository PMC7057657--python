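"""Local covariance eigen-features on point clouds.

For a point ``x`` the neighbourhood is the strict-radius ball
``N_x = {x_i : ||x - x_i|| < d}`` (the query point itself is included, its
distance being 0).  The sample covariance of the neighbourhood (unbiased,
``|N|-1`` normalisation) has eigenvalues ``λ1 ≤ λ2 ≤ λ3`` whose relative
magnitudes separate sheet-like (leaf) from line-like (stem) surfaces:

* curvature (surface variation) ``C = λ1 / (λ1 + λ2 + λ3)`` ∈ [0, 1/3] —
  0 on a flat sheet, 1/3 for an isotropic neighbourhood;
* flatness ``R = ln(max(C, c_eps))`` ∈ [ln c_eps, ln 1/3], the unary evidence
  used by the graph-cut segmenter;
* the four eigenvalue ratios ``F1 = λ1/√(λ2 λ3)``, ``F2 = λ2/λ3``,
  ``F3 = λ1/√(λ1 λ2 λ3)``, ``F4 = λ1/λ2`` used, concatenated over several
  neighbourhood radii, as the feature vector of the supervised classifier.

All descriptors are invariant to rigid motion of the cloud; eigenvalues scale
as ``s²`` under uniform scaling by ``s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import LabeledPointCloud
from .errors import DegenerateNeighborhoodError, ValidationError

__all__ = [
    "DEFAULT_C_EPS",
    "DEFAULT_RADII",
    "EigenTriple",
    "MultiscaleFeatureTable",
    "radius_neighbors",
    "covariance_eigenvalues",
    "curvature",
    "flatness",
    "eigen_features",
    "batch_eigenvalues",
    "curvature_flatness",
    "multiscale_features",
]

#: Curvature floor used by both the flatness descriptor and the pairwise
#: penalty of the graph-cut segmenter.
DEFAULT_C_EPS = 0.015

#: Neighbourhood radii (mm) for the multi-scale feature vector.
DEFAULT_RADII = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0)

_EIG_CLAMP = 1e-12


@dataclass(frozen=True)
class EigenTriple:
    """Sorted eigenvalues (mm²) of a neighbourhood covariance matrix."""

    lambda1: float
    lambda2: float
    lambda3: float
    n_neighbors: int = 0

    def __post_init__(self) -> None:
        lams = (self.lambda1, self.lambda2, self.lambda3)
        if not (self.lambda1 <= self.lambda2 <= self.lambda3):
            raise ValidationError(f"eigenvalues must be sorted ascending, got {lams}")
        if self.lambda1 < -_EIG_CLAMP:
            raise ValidationError(f"negative eigenvalue {self.lambda1}")

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda1, self.lambda2, self.lambda3])


@dataclass
class MultiscaleFeatureTable:
    """Per-point eigen-features concatenated over neighbourhood radii.

    Columns are ordered ``F1..F4`` per radius, radii ascending, so the header
    reads ``F1_r2, F2_r2, ..., F4_r7`` for the default radii.
    """

    radii: tuple[float, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 * len(self.radii):
            raise ValidationError(
                f"feature matrix shape {self.matrix.shape} does not match "
                f"4 x {len(self.radii)} radii"
            )

    @property
    def column_names(self) -> list[str]:
        return [
            f"F{k}_r{r:g}" for r in self.radii for k in range(1, 5)
        ]

    def to_csv(self, path) -> None:
        np.savetxt(
            path, self.matrix, delimiter=",", comments="",
            header=",".join(self.column_names), fmt="%.10g",
        )


def radius_neighbors(cloud: LabeledPointCloud, query_index: int, d: float) -> np.ndarray:
    """Indices of points strictly within distance ``d`` of point ``query_index``.

    Includes the query point itself.  Strict inequality: a point at distance
    exactly ``d`` is excluded.
    """
    if d <= 0:
        raise ValidationError("neighbourhood radius must be positive")
    tree = cKDTree(cloud.coords)
    cand = np.array(sorted(tree.query_ball_point(cloud.coords[query_index], d)), dtype=np.int64)
    diffs = cloud.coords[cand] - cloud.coords[query_index]
    keep = np.einsum("ij,ij->i", diffs, diffs) < d * d
    return cand[keep]


def covariance_eigenvalues(neighbor_coords: np.ndarray) -> EigenTriple:
    """Ascending eigenvalues of the unbiased sample covariance of a point set."""
    pts = np.asarray(neighbor_coords, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"expected (n, 3) coordinates, got {pts.shape}")
    n = len(pts)
    if n < 2:
        raise DegenerateNeighborhoodError(
            f"need at least 2 points for a sample covariance, got {n}"
        )
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    lams = np.linalg.eigvalsh(cov)
    lams = np.where(lams < 0, np.where(lams >= -_EIG_CLAMP, 0.0, lams), lams)
    return EigenTriple(float(lams[0]), float(lams[1]), float(lams[2]), n_neighbors=n)


def curvature(eig: EigenTriple) -> float:
    """Surface variation ``λ1 / (λ1 + λ2 + λ3)``; 0 for a degenerate (zero) triple."""
    total = eig.lambda1 + eig.lambda2 + eig.lambda3
    if total == 0:
        return 0.0
    return eig.lambda1 / total


def flatness(curvature_value: float, c_eps: float = DEFAULT_C_EPS) -> float:
    """Flatness ``ln(max(C, c_eps))``, bounded in ``[ln c_eps, ln 1/3]``."""
    if not (-1e-9 <= curvature_value <= 1 / 3 + 1e-9):
        raise ValidationError(f"curvature {curvature_value} outside [0, 1/3]")
    return math.log(max(curvature_value, c_eps))


def eigen_features(eig: EigenTriple, eps: float = 1e-12) -> tuple[float, float, float, float]:
    """The four eigenvalue-ratio features ``(F1, F2, F3, F4)``.

    Denominators are floored at ``eps``; a feature with zero numerator is
    exactly 0 regardless of its denominator (keeps F3 continuous as λ1 → 0).
    """
    l1, l2, l3 = eig.lambda1, eig.lambda2, eig.lambda3

    def ratio(num: float, den: float) -> float:
        if num == 0.0:
            return 0.0
        return num / max(den, eps)

    return (
        ratio(l1, math.sqrt(l2 * l3)),
        ratio(l2, l3),
        ratio(l1, math.sqrt(l1 * l2 * l3)),
        ratio(l1, l2),
    )


# ---------------------------------------------------------------------------
# batched per-cloud computation


def batch_eigenvalues(
    cloud: LabeledPointCloud,
    radius: float,
    tree: cKDTree | None = None,
    chunk_size: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Covariance eigenvalues of every point's strict-radius neighbourhood.

    Returns ``(lams, counts)`` where ``lams`` is ``(N, 3)`` ascending
    eigenvalues (zeros where the neighbourhood has fewer than 2 points) and
    ``counts`` the neighbourhood sizes.  Neighbourhood moments are accumulated
    relative to the query point to avoid catastrophic cancellation.
    """
    coords = cloud.coords
    n = len(coords)
    if tree is None:
        tree = cKDTree(coords)
    lams = np.zeros((n, 3), dtype=np.float64)
    counts = np.zeros(n, dtype=np.int64)
    r2 = radius * radius
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        q = coords[start:stop]
        neigh = tree.query_ball_point(q, radius)
        lens = np.fromiter((len(m) for m in neigh), dtype=np.int64, count=stop - start)
        if lens.sum() == 0:
            continue
        idx = np.concatenate([np.asarray(m, dtype=np.int64) for m in neigh])
        qid = np.repeat(np.arange(stop - start), lens)
        diff = coords[idx] - q[qid]
        keep = np.einsum("ij,ij->i", diff, diff) < r2
        diff, qid = diff[keep], qid[keep]
        m = stop - start
        cnt = np.bincount(qid, minlength=m).astype(np.int64)
        counts[start:stop] = cnt
        s1 = np.empty((m, 3))
        for a in range(3):
            s1[:, a] = np.bincount(qid, weights=diff[:, a], minlength=m)
        s2 = np.empty((m, 3, 3))
        for a in range(3):
            for b in range(a, 3):
                v = np.bincount(qid, weights=diff[:, a] * diff[:, b], minlength=m)
                s2[:, a, b] = v
                s2[:, b, a] = v
        ok = cnt >= 2
        if not ok.any():
            continue
        cnt_ok = cnt[ok].astype(np.float64)
        mean = s1[ok] / cnt_ok[:, None]
        cov = (s2[ok] - cnt_ok[:, None, None] * mean[:, :, None] * mean[:, None, :])
        cov /= (cnt_ok - 1)[:, None, None]
        lam = np.linalg.eigvalsh(cov)
        lam[np.abs(lam) < _EIG_CLAMP] = 0.0
        np.maximum(lam, 0.0, out=lam)
        out = np.zeros((m, 3))
        out[ok] = lam
        lams[start:stop] = out
    return lams, counts


def curvature_flatness(
    cloud: LabeledPointCloud,
    radius: float = 3.0,
    c_eps: float = DEFAULT_C_EPS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point curvature and flatness arrays at one neighbourhood radius.

    Degenerate neighbourhoods (fewer than 2 points) get curvature 0, hence
    flatness ``ln(c_eps)``.
    """
    lams, _ = batch_eigenvalues(cloud, radius)
    total = lams.sum(axis=1)
    curv = np.where(total > 0, lams[:, 0] / np.where(total > 0, total, 1.0), 0.0)
    flat = np.log(np.maximum(curv, c_eps))
    return curv, flat


def _batch_features(lams: np.ndarray, counts: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Vectorised F1..F4; rows with fewer than 4 neighbours are all-zero."""
    l1, l2, l3 = lams[:, 0], lams[:, 1], lams[:, 2]
    f = np.zeros((len(lams), 4))
    with np.errstate(divide="ignore", invalid="ignore"):
        f[:, 0] = np.where(l1 == 0, 0.0, l1 / np.maximum(np.sqrt(l2 * l3), eps))
        f[:, 1] = np.where(l2 == 0, 0.0, l2 / np.maximum(l3, eps))
        f[:, 2] = np.where(l1 == 0, 0.0, l1 / np.maximum(np.sqrt(l1 * l2 * l3), eps))
        f[:, 3] = np.where(l1 == 0, 0.0, l1 / np.maximum(l2, eps))
    f[counts < 4] = 0.0
    return f


def multiscale_features(
    cloud: LabeledPointCloud,
    radii: Sequence[float] = DEFAULT_RADII,
) -> MultiscaleFeatureTable:
    """Concatenated ``F1..F4`` eigen-features at each neighbourhood radius.

    Neighbourhoods with fewer than 4 points (cannot span 3D) contribute an
    all-zero 4-vector at that radius.
    """
    if len(cloud) < 1:
        raise ValidationError("multiscale_features requires a non-empty cloud")
    radii = tuple(sorted(float(r) for r in radii))
    if any(r <= 0 for r in radii):
        raise ValidationError("all radii must be positive")
    tree = cKDTree(cloud.coords)
    blocks = []
    for r in radii:
        lams, counts = batch_eigenvalues(cloud, r, tree=tree)
        blocks.append(_batch_features(lams, counts))
    return MultiscaleFeatureTable(radii, np.hstack(blocks))
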