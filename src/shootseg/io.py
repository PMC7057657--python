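"""Readers and writers for point clouds, voxel volumes and manifests.

Point clouds travel as PLY (ASCII or binary little-endian, vertex element with
``x y z`` and an optional integer ``label`` property) or as whitespace XYZ text
(``x y z [label]`` per line).  Released clouds that encode the organ class as a
vertex colour can be decoded by passing a ``color_to_label`` map.

Volumes travel as multi-page TIFF stacks (one page per z-slice) with a JSON
sidecar ``{"spacing_mm": [sx, sy, sz], "value_kind": ...}``, or as a compressed
``.npz`` container used for fixtures and caches.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import tifffile
import yaml

from .core import DatasetManifest, LabeledPointCloud, ManifestEntry, VoxelGrid
from .errors import ValidationError

__all__ = [
    "load_point_cloud",
    "save_point_cloud",
    "load_volume",
    "save_volume",
    "load_manifest",
    "save_manifest",
]

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


# ---------------------------------------------------------------------------
# PLY

def _parse_ply_header(fh) -> tuple[str, list[tuple[str, int, list[tuple[str, str]]]]]:
    magic = fh.readline().strip()
    if magic != b"ply":
        raise ValidationError("not a PLY file (missing 'ply' magic)")
    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    while True:
        line = fh.readline()
        if not line:
            raise ValidationError("unterminated PLY header")
        tokens = line.decode("ascii").split()
        if not tokens or tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            fmt = tokens[1]
        elif tokens[0] == "element":
            elements.append((tokens[1], int(tokens[2]), []))
        elif tokens[0] == "property":
            if not elements:
                raise ValidationError("PLY property before any element")
            if tokens[1] == "list":
                # variable-length property (e.g. face indices); only supported
                # on skipped ASCII elements
                elements[-1][2].append(("__list__", tokens[-1]))
            else:
                if tokens[1] not in _PLY_DTYPES:
                    raise ValidationError(f"unsupported PLY property type {tokens[1]!r}")
                elements[-1][2].append((tokens[2], _PLY_DTYPES[tokens[1]]))
        elif tokens[0] == "end_header":
            break
    if fmt not in ("ascii", "binary_little_endian"):
        raise ValidationError(f"unsupported PLY format {fmt!r}")
    return fmt, elements


def _read_ply(path: Path) -> dict[str, np.ndarray]:
    with open(path, "rb") as fh:
        fmt, elements = _parse_ply_header(fh)
        vertex_data: Optional[np.ndarray] = None
        for name, count, props in elements:
            if any(p[0] == "__list__" for p in props):
                if name == "vertex":
                    raise ValidationError("list properties on the vertex element are unsupported")
                if fmt == "ascii":
                    for _ in range(count):
                        fh.readline()
                    continue
                raise ValidationError(f"cannot skip binary list element {name!r}")
            dtype = np.dtype([(pname, "<" + code) for pname, code in props])
            if fmt == "binary_little_endian":
                raw = fh.read(dtype.itemsize * count)
                if len(raw) != dtype.itemsize * count:
                    raise ValidationError(f"truncated PLY element {name!r}")
                data = np.frombuffer(raw, dtype=dtype, count=count)
            else:
                rows = [fh.readline().split() for _ in range(count)]
                data = np.zeros(count, dtype=dtype)
                for i, row in enumerate(rows):
                    if len(row) != len(props):
                        raise ValidationError(f"PLY ASCII row {i} has {len(row)} fields, expected {len(props)}")
                    data[i] = tuple(
                        float(v) if code.startswith("f") else int(v)
                        for v, (_, code) in zip(row, props)
                    )
            if name == "vertex":
                vertex_data = data
        if vertex_data is None:
            raise ValidationError("PLY file has no vertex element")
        return {n: np.ascontiguousarray(vertex_data[n]) for n in vertex_data.dtype.names}


def load_point_cloud(
    path: str | Path,
    format_hint: Optional[str] = None,
    color_to_label: Optional[Mapping[tuple[int, int, int], int]] = None,
) -> LabeledPointCloud:
    """Load a point cloud from PLY or XYZ text.

    Parameters
    ----------
    format_hint:
        ``"ply"`` or ``"xyz"``; inferred from the suffix when omitted.
    color_to_label:
        Optional ``{(r, g, b): organ_code}`` map used to decode colour-coded
        labels when the PLY has ``red/green/blue`` but no ``label`` property.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"point cloud file not found: {path}")
    fmt = format_hint or ("ply" if path.suffix.lower() == ".ply" else "xyz")
    if fmt == "ply":
        cols = _read_ply(path)
        for axis in ("x", "y", "z"):
            if axis not in cols:
                raise ValidationError(f"PLY vertex element lacks coordinate {axis!r}")
        coords = np.column_stack([cols["x"], cols["y"], cols["z"]]).astype(np.float64)
        labels = None
        if "label" in cols:
            labels = cols["label"].astype(np.int64)
        elif color_to_label is not None and all(c in cols for c in ("red", "green", "blue")):
            rgb = np.column_stack([cols["red"], cols["green"], cols["blue"]]).astype(int)
            labels = np.empty(len(rgb), dtype=np.int64)
            lut = {tuple(k): int(v) for k, v in color_to_label.items()}
            for i, key in enumerate(map(tuple, rgb)):
                if key not in lut:
                    raise ValidationError(f"vertex colour {key} not in color_to_label map")
                labels[i] = lut[key]
        return LabeledPointCloud(coords, labels)
    if fmt == "xyz":
        data = np.loadtxt(path, dtype=np.float64, ndmin=2)
        if data.size == 0:
            return LabeledPointCloud(np.empty((0, 3)))
        if data.shape[1] == 3:
            return LabeledPointCloud(data)
        if data.shape[1] == 4:
            return LabeledPointCloud(data[:, :3], data[:, 3].astype(np.int64))
        raise ValidationError(f"XYZ text must have 3 or 4 columns, got {data.shape[1]}")
    raise ValidationError(f"unknown point cloud format {fmt!r}")


def save_point_cloud(
    cloud: LabeledPointCloud,
    path: str | Path,
    format: Optional[str] = None,
    binary: bool = True,
) -> None:
    """Write a point cloud as PLY (coordinates stored as float64) or XYZ text."""
    path = Path(path)
    fmt = format or ("ply" if path.suffix.lower() == ".ply" else "xyz")
    if fmt == "xyz":
        if cloud.has_labels:
            data = np.column_stack([cloud.coords, cloud.labels])
            np.savetxt(path, data, fmt="%.17g %.17g %.17g %d")
        else:
            np.savetxt(path, cloud.coords, fmt="%.17g")
        return
    if fmt != "ply":
        raise ValidationError(f"unknown point cloud format {fmt!r}")
    n = len(cloud)
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"element vertex {n}")
    header += ["property double x", "property double y", "property double z"]
    if cloud.has_labels:
        header.append("property uchar label")
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            if cloud.has_labels:
                rec = np.zeros(n, dtype=np.dtype([("x", "<f8"), ("y", "<f8"), ("z", "<f8"), ("label", "u1")]))
                rec["x"], rec["y"], rec["z"] = cloud.coords.T
                rec["label"] = cloud.labels
            else:
                rec = np.zeros(n, dtype=np.dtype([("x", "<f8"), ("y", "<f8"), ("z", "<f8")]))
                rec["x"], rec["y"], rec["z"] = cloud.coords.T
            fh.write(rec.tobytes())
        else:
            for i in range(n):
                row = " ".join(repr(float(v)) for v in cloud.coords[i])
                if cloud.has_labels:
                    row += f" {int(cloud.labels[i])}"
                fh.write((row + "\n").encode("ascii"))


# ---------------------------------------------------------------------------
# volumes

_KIND_KEY = "value_kind"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a volume as multi-page TIFF (+ JSON sidecar) or ``.npz``."""
    path = Path(path)
    if path.suffix.lower() == ".npz":
        np.savez_compressed(
            path, values=grid.values, spacing=np.asarray(grid.spacing), kind=grid.kind
        )
        return
    if path.suffix.lower() in (".tif", ".tiff"):
        # internal axes are (x, y, z); TIFF pages are z-major (page = one slice)
        pages = np.ascontiguousarray(np.transpose(grid.values, (2, 1, 0)))
        tifffile.imwrite(path, pages)
        meta = {"spacing_mm": list(grid.spacing), _KIND_KEY: grid.kind}
        _sidecar_path(path).write_text(json.dumps(meta))
        return
    raise ValidationError(f"unknown volume format for {path.name!r} (use .tif/.tiff or .npz)")


def load_volume(path: str | Path) -> VoxelGrid:
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    if path.suffix.lower() == ".npz":
        with np.load(path) as data:
            return VoxelGrid(data["values"], tuple(data["spacing"]), kind=str(data["kind"]))
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            shapes = {p.shape for p in tf.pages}
            if len(shapes) > 1:
                raise ValidationError(f"TIFF stack has inconsistent page sizes: {sorted(shapes)}")
            pages = tf.asarray()
        if pages.ndim == 2:
            pages = pages[None]
        values = np.transpose(pages, (2, 1, 0))
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            spacing = tuple(meta["spacing_mm"])
            kind = meta.get(_KIND_KEY, "intensity")
        else:
            spacing, kind = (1.0, 1.0, 1.0), "intensity"
        return VoxelGrid(values, spacing, kind=kind)
    raise ValidationError(f"unknown volume format for {path.name!r}")


# ---------------------------------------------------------------------------
# manifests


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    doc = [
        {
            "model_id": e.model_id,
            "cloud": str(e.cloud_path),
            "volume": str(e.volume_path),
            "role": e.role,
        }
        for e in manifest.entries
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    if not path.exists():
        raise IOError(f"manifest file not found: {path}")
    doc = yaml.safe_load(path.read_text()) or []
    entries = [
        ManifestEntry(
            model_id=str(d["model_id"]),
            cloud_path=Path(d["cloud"]),
            volume_path=Path(d["volume"]),
            role=d["role"],
        )
        for d in doc
    ]
    for e in entries:
        if e.role not in ("train", "test"):
            raise ValidationError(f"manifest entry {e.model_id}: bad role {e.role!r}")
    return DatasetManifest(entries)
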