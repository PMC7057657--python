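"""Seeded generator of labeled 3D plant phantoms.

A phantom emulates the geometric regime of X-ray CT rosebush models: stems,
branches and petioles are rounded tubes (sub-millimetre to a few millimetres
in radius) and leaves are thin curved sheets (~0.6 mm), sampled on a voxel
grid at 0.5 mm isotropic spacing.  Each phantom is produced in two forms that
stay exactly consistent: a dense organ-label voxel grid and the surface point
cloud derived from it (one point per surface voxel, labels inherited).

Construction: a trunk grows upward as a biased random walk; lateral branches
start on the trunk; each compound leaf is a petiole (labeled stem, as petioles
share the stem class) carrying opposite leaflet pairs plus a terminal leaflet.
Leaflets are extruded ellipses with a slight droop.  At stem/leaf collisions
the stem label wins, which keeps petiole connectivity intact — opposite
leaflets squeezing a petiole is the hard case the baselines are meant to face.

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import (
    DatasetManifest,
    LabeledPointCloud,
    ManifestEntry,
    OrganLabel,
    VoxelGrid,
    extract_surface,
    voxels_to_points,
)
from .errors import ValidationError
from .io import save_manifest, save_point_cloud, save_volume

__all__ = ["PhantomSpec", "PhantomModel", "generate_phantom", "make_benchmark_suite"]

# a rasterisation radius below half the voxel diagonal can break a thin tube
# into disconnected voxels; clamp to keep the stem 26-connected
_MIN_RASTER_RADIUS = 0.55


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and sampling parameters of one synthetic plant.

    Lengths and radii in mm.  The defaults give compact shoots (grids of
    roughly 1–2 million voxels, surface clouds of 15–25 thousand points)
    whose leaf/stem voxel fractions fall in the regime reported for real
    rosebush CT models (leaf roughly 70–80 % of shoot voxels, stem 12–22 %).
    """

    n_branches: int = 3
    trunk_length_range: tuple[float, float] = (22.0, 30.0)
    branch_length_range: tuple[float, float] = (16.0, 26.0)
    branch_radius_range: tuple[float, float] = (1.0, 2.5)
    petiole_radius_range: tuple[float, float] = (0.4, 0.9)
    petiole_length_range: tuple[float, float] = (12.0, 18.0)
    leaves_per_branch: int = 2
    leaflet_pairs: int = 1
    leaflet_semiaxis_a_range: tuple[float, float] = (7.0, 12.0)
    leaflet_semiaxis_b_range: tuple[float, float] = (4.5, 7.0)
    leaf_thickness: float = 0.6
    up_bias: float = 0.5
    step_length: float = 2.5
    include_flowers: bool = False
    flower_radius_range: tuple[float, float] = (2.5, 4.0)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "trunk_length_range",
            "branch_length_range",
            "branch_radius_range",
            "petiole_radius_range",
            "petiole_length_range",
            "leaflet_semiaxis_a_range",
            "leaflet_semiaxis_b_range",
            "flower_radius_range",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must be positive and ordered, got {(lo, hi)}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")
        if self.leaf_thickness <= 0 or self.step_length <= 0:
            raise ValidationError("leaf_thickness and step_length must be positive")


@dataclass
class PhantomModel:
    """A generated phantom: dense labels, surface forms, and ground truth."""

    label_grid: VoxelGrid  # full volume organ labels
    surface_grid: VoxelGrid  # organ labels restricted to surface voxels
    cloud: LabeledPointCloud  # surface point cloud, labels inherited
    components: dict = field(default_factory=dict)

    @property
    def shoot_voxel_count(self) -> int:
        return int((self.label_grid.values != 0).sum())

    def class_fraction(self, label: OrganLabel) -> float:
        total = self.shoot_voxel_count
        return float((self.label_grid.values == int(label)).sum() / total) if total else 0.0


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _random_walk(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    step: float,
    up_bias: float,
    wobble: float = 0.35,
) -> np.ndarray:
    """Polyline of a branch: noisy steps pulled toward the vertical."""
    points = [start.astype(float)]
    d = _unit(direction)
    n_steps = max(2, int(round(length / step)))
    for _ in range(n_steps):
        d = _unit(d + up_bias * step / length * np.array([0, 0, 1.0]) + wobble * rng.normal(size=3) * 0.3)
        points.append(points[-1] + d * step)
    return np.asarray(points)


def _perpendicular(d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e = _unit(np.cross(d, ref))
    phi = rng.uniform(0, 2 * np.pi)
    return _unit(np.cos(phi) * e + np.sin(phi) * _unit(np.cross(d, e)))


@dataclass
class _Leaflet:
    center: np.ndarray
    e1: np.ndarray  # along blade
    e2: np.ndarray  # across blade
    e3: np.ndarray  # normal
    a: float
    b: float
    thickness: float
    droop: float  # sagitta of the quadratic bend at |u| = a


def _build_skeleton(spec: PhantomSpec, rng: np.random.Generator):
    """Sample trunk/branch polylines, petioles, leaflets and flower blobs."""
    tubes: list[tuple[np.ndarray, float]] = []  # (polyline, radius)
    leaflets: list[_Leaflet] = []
    flowers: list[tuple[np.ndarray, float]] = []
    branch_records = []

    trunk_len = rng.uniform(*spec.trunk_length_range)
    trunk = _random_walk(
        rng, np.zeros(3), np.array([0.05, 0.05, 1.0]), trunk_len, spec.step_length, spec.up_bias * 2
    )
    # plants of the same cultivar and age have similar trunk calibre; draw the
    # trunk from the top quarter of the branch-radius range
    _, r_hi = spec.branch_radius_range
    trunk_radius = rng.uniform(0.75 * r_hi, r_hi)
    tubes.append((trunk, trunk_radius))
    branch_records.append({"kind": "trunk", "polyline": trunk, "radius": trunk_radius})

    def polyline_point(poly: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
        seg = min(int(frac * (len(poly) - 1)), len(poly) - 2)
        t = frac * (len(poly) - 1) - seg
        p = poly[seg] * (1 - t) + poly[seg + 1] * t
        d = _unit(poly[seg + 1] - poly[seg])
        return p, d

    def add_compound_leaf(host: np.ndarray, frac: float) -> None:
        attach, host_dir = polyline_point(host, frac)
        side = _perpendicular(host_dir, rng)
        pet_dir = _unit(side + np.array([0, 0, rng.uniform(0.4, 0.9)]))
        pet_len = rng.uniform(*spec.petiole_length_range)
        pet_radius = rng.uniform(*spec.petiole_radius_range)
        petiole = np.array([attach, attach + pet_dir * pet_len * 0.5, attach + pet_dir * pet_len])
        tubes.append((petiole, pet_radius))

        def add_leaflet(base: np.ndarray, direction: np.ndarray) -> None:
            a = rng.uniform(*spec.leaflet_semiaxis_a_range)
            b = rng.uniform(*spec.leaflet_semiaxis_b_range)
            e1 = _unit(direction)
            e3 = _unit(np.cross(e1, _perpendicular(e1, rng)) + np.array([0, 0, 1.5]))
            e3 = _unit(e3 - e1 * (e3 @ e1))
            e2 = _unit(np.cross(e3, e1))
            # centre pulled 1 mm inside the attachment so blade and stem overlap
            center = base + e1 * (a - 1.0)
            leaflets.append(
                _Leaflet(center, e1, e2, e3, a, b, spec.leaf_thickness, droop=0.12 * a)
            )

        # terminal leaflet continues the petiole; opposite pairs sit lower on
        # it and point sideways, so the blades stay mostly separated
        tip = petiole[-1]
        add_leaflet(tip, _unit(pet_dir + np.array([0, 0, -0.15])))
        for k in range(spec.leaflet_pairs):
            fr = 0.3 + 0.35 * k / max(spec.leaflet_pairs - 1, 1)
            base, d = polyline_point(petiole, fr)
            wing = _unit(np.cross(d, _perpendicular(d, rng)))
            for sgn in (+1.0, -1.0):
                add_leaflet(base, _unit(sgn * wing + 0.25 * d + np.array([0, 0, 0.15])))

    azimuths = rng.permutation(spec.n_branches) * (2 * np.pi / max(spec.n_branches, 1))
    for bi in range(spec.n_branches):
        frac = rng.uniform(0.35, 0.95)
        start, _ = polyline_point(trunk, frac)
        phi = azimuths[bi] + rng.uniform(-0.4, 0.4)
        tilt = rng.uniform(0.65, 1.05)  # radians from vertical
        d0 = np.array([np.sin(tilt) * np.cos(phi), np.sin(tilt) * np.sin(phi), np.cos(tilt)])
        blen = rng.uniform(*spec.branch_length_range)
        bradius = rng.uniform(spec.branch_radius_range[0], trunk_radius)
        poly = _random_walk(rng, start, d0, blen, spec.step_length, spec.up_bias)
        tubes.append((poly, bradius))
        branch_records.append({"kind": "branch", "polyline": poly, "radius": bradius})
        # evenly spaced attachment points with jitter keep compound leaves apart
        fracs = np.linspace(0.4, 1.0, spec.leaves_per_branch)
        for li in range(spec.leaves_per_branch):
            add_compound_leaf(poly, float(np.clip(fracs[li] + rng.uniform(-0.08, 0.08), 0.1, 1.0)))
        if spec.include_flowers and rng.uniform() < 0.5:
            flowers.append((poly[-1], rng.uniform(*spec.flower_radius_range)))

    for li in range(max(0, spec.leaves_per_branch - 1)):
        add_compound_leaf(trunk, rng.uniform(0.55, 1.0))

    return tubes, leaflets, flowers, branch_records


def _leaflet_candidates(lf: _Leaflet) -> list[_Leaflet]:
    """Deterministic pitch variants of a blade, hinged at its attachment.

    Interpenetrating blades are nonphysical (real foliage touches but does not
    cross); rasterisation tries these pitches in order and keeps the first one
    whose overlap with already-placed leaf material is small.
    """
    base = lf.center - lf.e1 * (lf.a - 1.0)
    out = []
    for theta in (0.0, 0.35, -0.35, 0.7, -0.7, 1.05, -1.05):
        c, s = np.cos(theta), np.sin(theta)
        e1 = c * lf.e1 + s * lf.e3
        e3 = -s * lf.e1 + c * lf.e3
        out.append(
            _Leaflet(base + e1 * (lf.a - 1.0), e1, lf.e2, e3, lf.a, lf.b, lf.thickness, lf.droop)
        )
    return out


def _rasterize(spec: PhantomSpec, tubes, leaflets, flowers):
    spacing = np.asarray(spec.spacing)
    margin = 3.0

    mins, maxs = [], []
    for poly, r in tubes:
        mins.append(poly.min(axis=0) - r)
        maxs.append(poly.max(axis=0) + r)
    for lf0 in leaflets:
        for lf in _leaflet_candidates(lf0):
            ext = (
                np.abs(lf.e1) * lf.a
                + np.abs(lf.e2) * lf.b
                + np.abs(lf.e3) * (lf.thickness / 2 + lf.droop)
            )
            mins.append(lf.center - ext)
            maxs.append(lf.center + ext)
    for c, r in flowers:
        mins.append(c - r)
        maxs.append(c + r)
    lo = np.min(mins, axis=0) - margin
    hi = np.max(maxs, axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int)

    stem = np.zeros(shape, dtype=bool)
    leaf = np.zeros(shape, dtype=bool)
    flower = np.zeros(shape, dtype=bool)

    def subbox(p_lo: np.ndarray, p_hi: np.ndarray):
        i0 = np.maximum(np.floor((p_lo - lo) / spacing - 0.5).astype(int), 0)
        i1 = np.minimum(np.ceil((p_hi - lo) / spacing + 0.5).astype(int), shape - 1)
        if (i1 < i0).any():
            return None
        grids = np.meshgrid(
            *(np.arange(i0[a], i1[a] + 1) for a in range(3)), indexing="ij"
        )
        idx = np.stack([g.ravel() for g in grids], axis=1)
        centers = lo + (idx + 0.5) * spacing
        return idx, centers

    def paint(mask: np.ndarray, idx: np.ndarray, hit: np.ndarray) -> None:
        sel = idx[hit]
        mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True

    for poly, radius in tubes:
        r = max(radius, _MIN_RASTER_RADIUS)
        for p0, p1 in zip(poly[:-1], poly[1:]):
            box = subbox(np.minimum(p0, p1) - r, np.maximum(p0, p1) + r)
            if box is None:
                continue
            idx, centers = box
            seg = p1 - p0
            seg_len2 = float(seg @ seg)
            if seg_len2 == 0:
                d2 = ((centers - p0) ** 2).sum(axis=1)
            else:
                t = np.clip((centers - p0) @ seg / seg_len2, 0.0, 1.0)
                proj = p0 + t[:, None] * seg
                d2 = ((centers - proj) ** 2).sum(axis=1)
            paint(stem, idx, d2 <= r * r)

    half_t = 0.5 * max(spec.leaf_thickness, 2 * _MIN_RASTER_RADIUS * 0.55)

    def blade_voxels(lf: _Leaflet, inflate: float = 0.0):
        ext = (
            np.abs(lf.e1) * (lf.a + inflate)
            + np.abs(lf.e2) * (lf.b + inflate)
            + np.abs(lf.e3) * (half_t + inflate + lf.droop + 0.5)
        )
        box = subbox(lf.center - ext, lf.center + ext)
        if box is None:
            return None
        idx, centers = box
        rel = centers - lf.center
        u = rel @ lf.e1
        v = rel @ lf.e2
        w = rel @ lf.e3
        bend = lf.droop * (u / lf.a) ** 2
        hit = (
            (u / (lf.a + inflate)) ** 2 + (v / (lf.b + inflate)) ** 2 <= 1.0
        ) & (np.abs(w - bend) <= half_t + inflate)
        return idx[hit]

    # Proximity map: everything within ~2 mm of already-placed material.
    # Blades are placed one at a time and pitch away from it, so foliage may
    # touch but rarely crosses or stacks tightly — as in a real canopy, where
    # interpenetrating blades are impossible.
    clearance_vox = np.maximum(np.rint(2.0 / spacing).astype(int) * 2 + 1, 3)
    prox = ndimage.maximum_filter(stem, size=tuple(clearance_vox)).astype(bool)
    for lf0 in leaflets:
        best, best_score = None, np.inf
        for cand in _leaflet_candidates(lf0):
            sel = blade_voxels(cand)
            if sel is None or len(sel) == 0:
                continue
            score = prox[sel[:, 0], sel[:, 1], sel[:, 2]].mean()
            if score < best_score:
                best, best_score = (cand, sel), score
            if score <= 0.10:
                break
        if best is None:
            continue
        cand, sel = best
        leaf[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        halo = blade_voxels(cand, inflate=2.0)
        if halo is not None:
            prox[halo[:, 0], halo[:, 1], halo[:, 2]] = True

    for c, r in flowers:
        box = subbox(c - r, c + r)
        if box is None:
            continue
        idx, centers = box
        paint(flower, idx, ((centers - c) ** 2).sum(axis=1) <= r * r)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[flower] = int(OrganLabel.FLOWER)
    labels[leaf] = int(OrganLabel.LEAF)
    labels[stem] = int(OrganLabel.STEM)  # stem wins at overlaps

    # crop to content + margin (the provisional bbox covers every candidate
    # blade pitch, most of which were not used)
    nz = np.argwhere(labels != 0)
    pad = np.rint(margin / spacing).astype(int)
    lo_i = np.maximum(nz.min(axis=0) - pad, 0)
    hi_i = np.minimum(nz.max(axis=0) + pad + 1, shape)
    return labels[lo_i[0]:hi_i[0], lo_i[1]:hi_i[1], lo_i[2]:hi_i[2]]


def generate_phantom(spec: PhantomSpec) -> PhantomModel:
    """Generate a labeled plant phantom. Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    tubes, leaflets, flowers, branch_records = _build_skeleton(spec, rng)
    labels = _rasterize(spec, tubes, leaflets, flowers)
    if not labels.any():
        raise ValidationError("spec produced an empty plant")
    label_grid = VoxelGrid(labels, spec.spacing, kind="label")

    shoot = VoxelGrid((labels != 0).astype(np.uint8), spec.spacing, kind="binary_mask")
    surface = extract_surface(shoot)
    surface_labels = np.where(surface.values != 0, labels, 0).astype(np.uint8)
    surface_grid = VoxelGrid(surface_labels, spec.spacing, kind="label")
    cloud = voxels_to_points(surface_grid)
    return PhantomModel(
        label_grid=label_grid,
        surface_grid=surface_grid,
        cloud=cloud,
        components={
            "branches": branch_records,
            "n_leaflets": len(leaflets),
            "n_flowers": len(flowers),
            "seed": spec.seed,
        },
    )


def stem_component_count(model: PhantomModel) -> int:
    """Number of 26-connected components of the stem voxels (should be 1)."""
    structure = ndimage.generate_binary_structure(3, 3)
    _, n = ndimage.label(model.label_grid.values == int(OrganLabel.STEM), structure=structure)
    return int(n)


def make_benchmark_suite(
    n_models: int,
    base_seed: int,
    out_dir: str | Path,
    spec: Optional[PhantomSpec] = None,
) -> DatasetManifest:
    """Write ``n_models`` phantoms to disk; model 1 is the train model.

    Model ``m`` uses seed ``base_seed + m - 1`` of the shared spec, mirroring
    a train-on-one-model / test-on-the-rest protocol.  Deterministic: the same
    call produces identical files.
    """
    if n_models < 2:
        raise ValidationError("a benchmark suite needs at least 2 models (1 train + tests)")
    spec = spec or PhantomSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for m in range(1, n_models + 1):
        model_dir = out_dir / f"model_{m:02d}"
        model_dir.mkdir(exist_ok=True)
        phantom = generate_phantom(replace(spec, seed=base_seed + m - 1))
        cloud_path = model_dir / "surface_cloud.ply"
        volume_path = model_dir / "surface_labels.tif"
        save_point_cloud(phantom.cloud, cloud_path)
        save_volume(phantom.surface_grid, volume_path)
        entries.append(
            ManifestEntry(
                model_id=f"model_{m:02d}",
                cloud_path=cloud_path,
                volume_path=volume_path,
                role="train" if m == 1 else "test",
            )
        )
    manifest = DatasetManifest(entries)
    save_manifest(manifest, out_dir / "manifest.yaml")
    return manifest
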