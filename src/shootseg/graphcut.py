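"""Unsupervised leaf/stem segmentation by binary MRF graph-cut (LFPC-u).

The point cloud is organised as a graph: nodes are points, and two points are
joined by an edge when their Euclidean distance is strictly below a threshold
(default 1.4 mm).  A binary labeling ``f`` assigning each point leaf (L) or
stem (S) is scored by the energy

    E(f) = w_D * Σ_x D_x(f(x)) + w_V * Σ_(i,j) V(f(i), f(j))

where the data term uses the flatness descriptor R ∈ [R_L, R_S]
(``D_x(L) = R - R_L``, ``D_x(S) = R_S - R``: flat points are cheap to call
leaf) and the pairwise term penalises label disagreement across an edge by
``max(1/C_i, 1/C_j)`` — smooth surfaces (low curvature) are expensive to cut
through, part boundaries (high curvature) are cheap.  The curvature inside
the pairwise reciprocal is floored at ``c_eps`` so the penalty stays finite
on perfectly flat regions.

With non-negative pairwise penalties the energy is submodular, so the global
minimum is found exactly by an s-t min-cut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from scipy.spatial import cKDTree

from .core import LabeledPointCloud, OrganLabel
from .errors import ValidationError
from .features import DEFAULT_C_EPS, curvature_flatness

__all__ = [
    "LABEL_LEAF",
    "LABEL_STEM",
    "MRFProblem",
    "BinaryLabeling",
    "build_graph",
    "data_term",
    "smoothness_term",
    "energy",
    "minimize_energy",
    "segment_lfpc_u",
]

LABEL_LEAF = 0
LABEL_STEM = 1

# fixed-point scale for max-flow capacities (see minimize_energy)
_CAPACITY_SCALE = float(2**26)


def flatness_bounds(c_eps: float = DEFAULT_C_EPS) -> tuple[float, float]:
    """The flatness range ``(R_L, R_S) = (ln c_eps, ln 1/3)``."""
    return math.log(c_eps), math.log(1.0 / 3.0)


@dataclass
class MRFProblem:
    """A binary pairwise labeling problem with Potts smoothness.

    ``unary[i] = (cost_L, cost_S)``; ``pairwise[e]`` is the non-negative
    penalty paid when the endpoints of edge ``e`` disagree.  The weights
    ``w_D`` / ``w_V`` multiply the data and smoothness sums.
    """

    n_nodes: int
    edges: np.ndarray
    unary: np.ndarray
    pairwise: np.ndarray
    w_D: float = 0.9
    w_V: float = 0.1

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.unary = np.asarray(self.unary, dtype=np.float64).reshape(-1, 2)
        self.pairwise = np.asarray(self.pairwise, dtype=np.float64).reshape(-1)
        if self.unary.shape[0] != self.n_nodes:
            raise ValidationError(
                f"unary has {self.unary.shape[0]} rows for {self.n_nodes} nodes"
            )
        if len(self.pairwise) != len(self.edges):
            raise ValidationError("pairwise length must equal number of edges")
        if len(self.edges):
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise ValidationError("edge indices out of range")
            if (self.edges[:, 0] >= self.edges[:, 1]).any():
                raise ValidationError("edges must satisfy i < j")
            packed = self.edges[:, 0] * self.n_nodes + self.edges[:, 1]
            if len(np.unique(packed)) != len(packed):
                raise ValidationError("duplicate edges")
        if (self.pairwise < 0).any():
            raise ValidationError("pairwise penalties must be non-negative (submodularity)")
        if self.w_D < 0 or self.w_V < 0:
            raise ValidationError("weights must be non-negative")


@dataclass
class BinaryLabeling:
    """A leaf/stem labeling together with its energy under the problem."""

    labels: np.ndarray  # values in {LABEL_LEAF, LABEL_STEM}
    energy: float


def build_graph(cloud: LabeledPointCloud, edge_distance: float = 1.4) -> np.ndarray:
    """Undirected deduplicated edge list ``(E, 2)`` with ``i < j``.

    A pair is an edge iff its Euclidean distance is strictly less than
    ``edge_distance`` (mm).  Isolated nodes are permitted.
    """
    if edge_distance <= 0:
        raise ValidationError("edge_distance must be positive")
    tree = cKDTree(cloud.coords)
    pairs = tree.query_pairs(edge_distance, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    diffs = cloud.coords[pairs[:, 0]] - cloud.coords[pairs[:, 1]]
    keep = np.einsum("ij,ij->i", diffs, diffs) < edge_distance**2
    pairs = pairs[keep].astype(np.int64)
    pairs = np.sort(pairs, axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


def data_term(flatness_value: float, c_eps: float = DEFAULT_C_EPS) -> tuple[float, float]:
    """Unary costs ``(cost_L, cost_S) = (R - R_L, R_S - R)``.

    Both costs are non-negative and sum to the constant ``R_S - R_L``.
    """
    r_l, r_s = flatness_bounds(c_eps)
    if not (r_l - 1e-9 <= flatness_value <= r_s + 1e-9):
        raise ValidationError(f"flatness {flatness_value} outside [{r_l}, {r_s}]")
    return flatness_value - r_l, r_s - flatness_value


def smoothness_term(curv_i: float, curv_j: float, c_eps: float = DEFAULT_C_EPS) -> float:
    """Disagreement penalty ``max(1/C'_i, 1/C'_j)`` with ``C' = max(C, c_eps)``.

    The floor keeps the penalty finite (≤ 1/c_eps) on flat regions; the cost
    for agreeing labels is 0 by construction of the energy.
    """
    for c in (curv_i, curv_j):
        if not (-1e-9 <= c <= 1 / 3 + 1e-9):
            raise ValidationError(f"curvature {c} outside [0, 1/3]")
    return max(1.0 / max(curv_i, c_eps), 1.0 / max(curv_j, c_eps))


def energy(problem: MRFProblem, labels: np.ndarray) -> float:
    """Evaluate the MRF energy of a labeling."""
    labels = np.asarray(labels, dtype=np.int64)
    data = problem.unary[np.arange(problem.n_nodes), labels].sum()
    smooth = 0.0
    if len(problem.edges):
        differ = labels[problem.edges[:, 0]] != labels[problem.edges[:, 1]]
        smooth = float(problem.pairwise[differ].sum())
    return problem.w_D * float(data) + problem.w_V * smooth


def minimize_energy(problem: MRFProblem) -> BinaryLabeling:
    """Exact global minimiser of the binary Potts energy via s-t min-cut.

    Terminal capacities carry the unaries, edge capacities the (symmetric)
    pairwise penalties; the cut side of each node gives its label.  Costs are
    converted to fixed-point integers (scale 2^26) for the max-flow solver;
    the returned energy is re-evaluated in floating point from the labeling.
    """
    n = problem.n_nodes
    src, snk = n, n + 1
    cap_l = problem.w_D * problem.unary[:, LABEL_LEAF]
    cap_s = problem.w_D * problem.unary[:, LABEL_STEM]
    cap_e = problem.w_V * problem.pairwise

    rows, cols, caps = [], [], []
    nodes = np.arange(n)
    # node on source side => leaf; cutting i->sink pays cost_L, source->i pays cost_S
    rows.append(np.full(n, src)); cols.append(nodes); caps.append(cap_s)
    rows.append(nodes); cols.append(np.full(n, snk)); caps.append(cap_l)
    if len(problem.edges):
        i, j = problem.edges[:, 0], problem.edges[:, 1]
        rows += [i, j]
        cols += [j, i]
        caps += [cap_e, cap_e]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    caps_int = np.rint(np.concatenate(caps) * _CAPACITY_SCALE).astype(np.int64)

    graph = csr_matrix((caps_int, (rows, cols)), shape=(n + 2, n + 2))
    result = maximum_flow(graph, src, snk)
    residual = graph - result.flow
    residual.data = (residual.data > 0).astype(np.int64)
    residual.eliminate_zeros()
    reachable = breadth_first_order(residual, src, directed=True, return_predecessors=False)
    labels = np.full(n, LABEL_STEM, dtype=np.int64)
    labels[reachable[reachable < n]] = LABEL_LEAF
    return BinaryLabeling(labels, energy(problem, labels))


def build_problem(
    curvatures: np.ndarray,
    flatnesses: np.ndarray,
    edges: np.ndarray,
    w_D: float = 0.9,
    w_V: float = 0.1,
    c_eps: float = DEFAULT_C_EPS,
) -> MRFProblem:
    """Assemble the MRF from per-point descriptors and an edge list."""
    r_l, r_s = flatness_bounds(c_eps)
    flatnesses = np.clip(np.asarray(flatnesses, dtype=np.float64), r_l, r_s)
    unary = np.column_stack([flatnesses - r_l, r_s - flatnesses])
    cflo = np.maximum(np.asarray(curvatures, dtype=np.float64), c_eps)
    if len(edges):
        pairwise = np.maximum(1.0 / cflo[edges[:, 0]], 1.0 / cflo[edges[:, 1]])
    else:
        pairwise = np.empty(0)
    return MRFProblem(len(unary), edges, unary, pairwise, w_D=w_D, w_V=w_V)


def _grid_downsample(coords: np.ndarray, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """One representative point per occupied voxel of pitch ``pitch`` (mm).

    Returns (representative indices, cell id per original point).
    """
    cells = np.floor(coords / pitch).astype(np.int64)
    _, reps, inverse = np.unique(cells, axis=0, return_index=True, return_inverse=True)
    return reps, inverse


def segment_lfpc_u(
    cloud: LabeledPointCloud,
    d_curvature: float = 3.0,
    edge_distance: float = 1.4,
    w_D: float = 0.9,
    w_V: float = 0.1,
    c_eps: float = DEFAULT_C_EPS,
    downsample_mm: float | None = None,
) -> np.ndarray:
    """Unsupervised leaf/stem labels for every point of a cloud.

    Pipeline: per-point curvature/flatness at radius ``d_curvature`` →
    neighbourhood graph at ``edge_distance`` → MRF assembly → exact min-cut.
    Returns organ codes (leaf/stem) per point.

    ``downsample_mm`` (off by default) segments one representative point per
    voxel of that pitch and propagates labels back to all cell members — a
    speed option for very large clouds.
    """
    if len(cloud) < 1:
        raise ValidationError("cannot segment an empty cloud")
    if downsample_mm is not None:
        if downsample_mm <= 0:
            raise ValidationError("downsample_mm must be positive")
        reps, inverse = _grid_downsample(cloud.coords, downsample_mm)
        rep_labels = segment_lfpc_u(
            LabeledPointCloud(cloud.coords[reps]),
            d_curvature=d_curvature,
            edge_distance=edge_distance,
            w_D=w_D,
            w_V=w_V,
            c_eps=c_eps,
        )
        return rep_labels[inverse]
    curv, flat = curvature_flatness(cloud, radius=d_curvature, c_eps=c_eps)
    edges = build_graph(cloud, edge_distance)
    problem = build_problem(curv, flat, edges, w_D=w_D, w_V=w_V, c_eps=c_eps)
    labeling = minimize_energy(problem)
    out = np.where(
        labeling.labels == LABEL_LEAF, int(OrganLabel.LEAF), int(OrganLabel.STEM)
    ).astype(np.int64)
    return out
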