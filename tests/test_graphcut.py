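import itertools
import math

import numpy as np
import pytest

from shootseg import (
    LabeledPointCloud,
    MRFProblem,
    OrganLabel,
    ValidationError,
    build_graph,
    data_term,
    energy,
    minimize_energy,
    segment_lfpc_u,
    smoothness_term,
)
from shootseg.graphcut import flatness_bounds

R_L, R_S = flatness_bounds()


def brute_force_minimum(problem):
    best = math.inf
    for labels in itertools.product((0, 1), repeat=problem.n_nodes):
        best = min(best, energy(problem, np.array(labels)))
    return best


def random_problem(rng, max_nodes=12):
    n = int(rng.integers(1, max_nodes + 1))
    all_pairs = list(itertools.combinations(range(n), 2))
    n_edges = int(rng.integers(0, len(all_pairs) + 1)) if all_pairs else 0
    sel = rng.choice(len(all_pairs), size=n_edges, replace=False) if n_edges else []
    edges = np.array([all_pairs[i] for i in sel], dtype=np.int64).reshape(-1, 2)
    return MRFProblem(
        n_nodes=n,
        edges=edges,
        unary=rng.uniform(0, 3.2, size=(n, 2)),
        pairwise=rng.uniform(0, 10, size=len(edges)),
        w_D=float(rng.uniform(0.1, 1.5)),
        w_V=float(rng.uniform(0.0, 1.0)),
    )


class TestBuildGraph:
    def test_collinear_chain(self):
        cloud = LabeledPointCloud(np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]))
        np.testing.assert_array_equal(build_graph(cloud, 1.4), [[0, 1], [1, 2]])

    def test_threshold_is_strict(self):
        cloud = LabeledPointCloud(np.array([[0.0, 0, 0], [1.4, 0, 0]]))
        assert len(build_graph(cloud, 1.4)) == 0

    def test_matches_brute_force_scan(self, rng):
        coords = rng.uniform(0, 6, size=(300, 3))
        edges = {tuple(e) for e in build_graph(LabeledPointCloud(coords), 1.0)}
        expected = {
            (i, j)
            for i in range(300)
            for j in range(i + 1, 300)
            if np.linalg.norm(coords[i] - coords[j]) < 1.0
        }
        assert edges == expected


class TestTerms:
    def test_data_term_extremes_and_midpoint(self):
        cost_l, cost_s = data_term(R_L)
        assert cost_l == 0
        assert cost_s == pytest.approx(3.10109, abs=1e-5)
        cost_l, cost_s = data_term(R_S)
        assert (cost_l, cost_s) == pytest.approx((R_S - R_L, 0), abs=1e-12)
        mid = (R_L + R_S) / 2
        cost_l, cost_s = data_term(mid)
        assert cost_l == pytest.approx(cost_s)
        with pytest.raises(ValidationError):
            data_term(R_S + 1.0)

    def test_data_costs_sum_to_constant(self, rng):
        for r in rng.uniform(R_L, R_S, size=20):
            cost_l, cost_s = data_term(float(r))
            assert cost_l >= 0 and cost_s >= 0
            assert cost_l + cost_s == pytest.approx(R_S - R_L)

    def test_smoothness_penalties(self):
        assert smoothness_term(1 / 3, 1 / 3) == pytest.approx(3.0)
        assert smoothness_term(0.0, 1 / 3) == pytest.approx(1 / 0.015)  # clamp active
        assert smoothness_term(0.1, 0.05) == pytest.approx(20.0)


class TestMinimizeEnergy:
    def test_isolated_flat_node_goes_leaf(self):
        problem = MRFProblem(1, np.empty((0, 2)), [[0.0, R_S - R_L]], [], w_D=1.0, w_V=0.1)
        sol = minimize_energy(problem)
        assert sol.labels[0] == 0 and sol.energy == 0

    def test_expensive_edge_forces_agreement(self):
        # opposing unaries but a cut costing 10: both nodes take one label
        problem = MRFProblem(
            2, [[0, 1]], [[0.0, 3.1], [3.1, 0.0]], [10.0], w_D=1.0, w_V=1.0
        )
        sol = minimize_energy(problem)
        assert sol.labels[0] == sol.labels[1]
        assert sol.energy == pytest.approx(3.1)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(40):
            problem = random_problem(rng, max_nodes=8)
            sol = minimize_energy(problem)
            assert sol.energy == pytest.approx(brute_force_minimum(problem), abs=1e-9)
            assert energy(problem, sol.labels) == pytest.approx(sol.energy, rel=1e-12)

    def test_zero_smoothness_reduces_to_pointwise_argmin(self, rng):
        problem = random_problem(rng)
        problem = MRFProblem(
            problem.n_nodes, problem.edges, problem.unary, problem.pairwise,
            w_D=problem.w_D, w_V=0.0,
        )
        sol = minimize_energy(problem)
        np.testing.assert_array_equal(sol.labels, np.argmin(problem.unary, axis=1))

    def test_zero_data_yields_zero_energy(self, rng):
        problem = random_problem(rng)
        problem = MRFProblem(
            problem.n_nodes, problem.edges, problem.unary, problem.pairwise,
            w_D=0.0, w_V=problem.w_V,
        )
        assert minimize_energy(problem).energy == pytest.approx(0.0, abs=1e-9)

    def test_stronger_smoothing_never_adds_disagreements(self, rng):
        def n_disagreements(problem):
            sol = minimize_energy(problem)
            e = problem.edges
            return int((sol.labels[e[:, 0]] != sol.labels[e[:, 1]]).sum()) if len(e) else 0

        for _ in range(10):
            base = random_problem(rng, max_nodes=10)
            counts = []
            for w_v in (0.0, 0.2, 0.6, 1.5):
                counts.append(
                    n_disagreements(
                        MRFProblem(base.n_nodes, base.edges, base.unary, base.pairwise,
                                   w_D=base.w_D, w_V=w_v)
                    )
                )
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_problem_validation(self):
        with pytest.raises(ValidationError):
            MRFProblem(2, [[1, 0]], np.zeros((2, 2)), [1.0])  # i >= j
        with pytest.raises(ValidationError):
            MRFProblem(2, [[0, 1], [0, 1]], np.zeros((2, 2)), [1.0, 1.0])  # duplicate
        with pytest.raises(ValidationError):
            MRFProblem(2, [[0, 1]], np.zeros((2, 2)), [-1.0])  # negative pairwise


def cylinder_cloud(radius, length, step=0.5):
    zs = np.arange(0, length, step)
    angles = np.arange(0, 2 * math.pi, step / radius)
    z, a = np.meshgrid(zs, angles)
    return LabeledPointCloud(
        np.column_stack([radius * np.cos(a).ravel(), radius * np.sin(a).ravel(), z.ravel()])
    )


def sheet_cloud(size=15.0, step=0.5):
    xs = np.arange(0, size, step)
    x, y = np.meshgrid(xs, xs)
    return LabeledPointCloud(
        np.column_stack([x.ravel(), y.ravel(), np.zeros(x.size)])
    )


class TestSegmentLfpcU:
    def test_flat_sheet_is_all_leaf(self):
        labels = segment_lfpc_u(sheet_cloud())
        assert (labels == int(OrganLabel.LEAF)).all()

    def test_thin_tube_is_mostly_stem(self):
        labels = segment_lfpc_u(cylinder_cloud(radius=1.0, length=30.0))
        assert (labels == int(OrganLabel.STEM)).mean() > 0.5

    def test_downsampled_segmentation_covers_all_points(self):
        cloud = sheet_cloud()
        labels = segment_lfpc_u(cloud, downsample_mm=1.0)
        assert labels.shape == (len(cloud),)
        assert (labels == int(OrganLabel.LEAF)).all()
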