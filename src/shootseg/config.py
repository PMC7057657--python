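"""Run configuration and reproducibility plumbing.

A single global seed fans out to per-stage seeds through a CRC32 hash of
``"<seed>:<stage>"`` so each stage (phantom generation, SVM, forest, ...)
is independently reproducible.  Every run writes a resolved-config snapshot
next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .features import DEFAULT_C_EPS, DEFAULT_RADII
from .volumetric import DEFAULT_SCALES

__all__ = ["RunConfig", "derive_seed", "load_config", "write_snapshot"]

try:  # package version for run snapshots
    from importlib.metadata import version

    _VERSION = version("shootseg")
except Exception:  # pragma: no cover
    _VERSION = "unknown"


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


@dataclass
class RunConfig:
    """All method parameters with their defaults.

    The graph-cut defaults (w_D=0.9, w_V=0.1, 1.4 mm edges, c_eps=0.015,
    3 mm curvature radius), the SVM radii (2–7 mm) and the filter-bank
    scales (0.7–10 mm) are the standard operating point of the three
    baselines; see docs/methods.md.
    """

    seed: int = 1
    # LFPC-u
    w_D: float = 0.9
    w_V: float = 0.1
    edge_distance: float = 1.4
    curvature_radius: float = 3.0
    c_eps: float = DEFAULT_C_EPS
    # LFPC-s
    radii: tuple[float, ...] = DEFAULT_RADII
    svm_C: float = 1.0
    standardize: bool = True
    # LFVD
    scales: tuple[float, ...] = DEFAULT_SCALES
    n_trees: int = 100

    def snapshot(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["radii"] = list(self.radii)
        doc["scales"] = list(self.scales)
        doc["package_version"] = _VERSION
        return doc


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON config; unknown keys are rejected."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - valid
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    if "radii" in doc:
        doc["radii"] = tuple(doc["radii"])
    if "scales" in doc:
        doc["scales"] = tuple(doc["scales"])
    return RunConfig(**doc)


def write_snapshot(config: RunConfig, out_dir: str | Path, extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = config.snapshot()
    if extra:
        doc.update(extra)
    path = out_dir / "run_config.json"
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    return path
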