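"""Connectome construction, Spearman and Blondel similarity."""

import numpy as np
import pytest
from scipy import stats

from protocol_lab.connectome import (
    Connectome,
    blondel_similarity,
    build_connectome,
    spearman_similarity,
    threshold_similarity,
)
from protocol_lab.phantom import RegionInfo
from protocol_lab.tracking import StreamlineSet


def _toy_connectome(weights, names=None):
    R = weights.shape[0]
    names = names or [f"L_r{i}" for i in range(R)]
    return Connectome(
        weights=np.asarray(weights, float),
        region_ids=list(range(1, R + 1)),
        region_names=names,
        hemispheres=[n.split("_")[0] for n in names],
    )


def _streamlines(paths, seed_regions, shape):
    if paths:
        pts = np.concatenate(paths).astype(np.float32)
    else:
        pts = np.empty((0, 3), dtype=np.float32)
    offsets = np.zeros(len(paths) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum([len(p) for p in paths])
    return StreamlineSet(pts, offsets, np.asarray(seed_regions, int), shape)


class TestBuild:
    regions = {
        1: RegionInfo(1, "L_a", "L", "gm"),
        2: RegionInfo(2, "L_b", "L", "gm"),
        3: RegionInfo(3, "R_a", "R", "gm"),
    }

    def _labels(self):
        labels = np.zeros((10, 3, 3), dtype=np.int16)
        labels[0:2] = 1
        labels[8:10] = 2
        return labels

    def test_single_bundle_counts(self):
        labels = self._labels()
        path = np.column_stack([np.arange(10), np.ones(10), np.ones(10)])
        sls = _streamlines([path, path[::-1]], [1, 1], labels.shape)
        conn = build_connectome(sls, labels, self.regions)
        i, j = conn.region_ids.index(1), conn.region_ids.index(2)
        # each streamline terminates once in region 1 and once in region 2:
        # 2 raw counts (1 -> 2), symmetrized to 1.0 on each side
        assert conn.weights[i, j] == conn.weights[j, i] == 1.0
        assert conn.weights[i, i] == 2.0  # termini at the seed end
        assert conn.weights[j, j] == 0.0
        assert conn.n_unassigned == 0

    def test_no_streamlines_zero_matrix(self):
        sls = _streamlines([], [], (10, 3, 3))
        conn = build_connectome(sls, self._labels(), self.regions)
        assert np.all(conn.weights == 0)

    def test_unassigned_endpoints_counted(self):
        labels = self._labels()
        labels[8:10] = 0  # far end unlabelled
        path = np.column_stack([np.arange(10), np.ones(10), np.ones(10)])
        sls = _streamlines([path], [1], labels.shape)
        conn = build_connectome(sls, labels, self.regions)
        assert conn.n_unassigned == 1

    def test_left_subgraph_filters_by_tag(self):
        conn = build_connectome(
            _streamlines([], [], (10, 3, 3)), self._labels(), self.regions
        )
        left = conn.subgraph("L")
        assert left.region_names == ["L_a", "L_b"]
        assert left.weights.shape == (2, 2)


class TestSpearman:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(0)
        w = rng.integers(0, 50, (6, 6)).astype(float)
        w = (w + w.T) / 2
        c = _toy_connectome(w)
        rho, p = spearman_similarity(c, c)
        assert rho == pytest.approx(1.0)

    def test_rank_reversal_is_minus_one(self):
        base = np.arange(10, dtype=float)
        iu = np.triu_indices(5, k=1)
        a = np.zeros((5, 5))
        b = np.zeros((5, 5))
        a[iu] = base
        b[iu] = base[::-1]
        a, b = a + a.T, b + b.T
        rho, _ = spearman_similarity(_toy_connectome(a), _toy_connectome(b))
        assert rho == pytest.approx(-1.0)

    def test_matches_manual_rank_transform(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 30, (5, 5)).astype(float)
        b = rng.integers(0, 30, (5, 5)).astype(float)
        a, b = (a + a.T) / 2, (b + b.T) / 2
        ca, cb = _toy_connectome(a), _toy_connectome(b)
        rho, _ = spearman_similarity(ca, cb)
        iu = np.triu_indices(5, k=1)
        ra = stats.rankdata(a[iu])  # average ranks for ties
        rb = stats.rankdata(b[iu])
        expect = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(expect, abs=1e-12)

    def test_constant_vector_rejected(self):
        c = _toy_connectome(np.ones((4, 4)))
        with pytest.raises(ValueError):
            spearman_similarity(c, c)

    def test_region_mismatch_rejected(self):
        a = _toy_connectome(np.eye(3))
        b = _toy_connectome(np.eye(3), names=["L_x", "L_y", "L_z"])
        with pytest.raises(ValueError):
            spearman_similarity(a, b)


class TestBlondel:
    def test_1x1_graphs(self):
        sim = blondel_similarity(np.array([[2.0]]), np.array([[5.0]]))
        assert sim.S == pytest.approx(np.array([[1.0]]))

    def test_same_graph_symmetric(self):
        rng = np.random.default_rng(2)
        A = rng.random((6, 6))
        sim = blondel_similarity(A, A, tol=1e-12, max_iter=2000)
        assert np.max(np.abs(sim.S - sim.S.T)) < 1e-10

    def test_unit_frobenius_norm_and_nonnegative(self):
        rng = np.random.default_rng(3)
        A, B = rng.random((4, 4)), rng.random((5, 5))
        sim = blondel_similarity(A, B)
        assert np.linalg.norm(sim.S) == pytest.approx(1.0, abs=1e-12)
        assert np.all(sim.S >= 0)

    def test_path3_vs_path4_matches_brute_force(self):
        """Even-iterate limit against a straightforward 10,000-step
        iteration written independently here."""
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1.0
        B = np.zeros((4, 4))
        for i in range(3):
            B[i, i + 1] = B[i + 1, i] = 1.0
        sim = blondel_similarity(A, B, tol=1e-12, max_iter=10_000)
        S = np.ones((4, 3))
        S /= np.linalg.norm(S)
        for _ in range(10_000):
            S = B @ S @ A.T + B.T @ S @ A
            S /= np.linalg.norm(S)
        assert np.max(np.abs(sim.S - S)) < 1e-8

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        A, B = rng.random((5, 5)), rng.random((5, 5))
        s1 = blondel_similarity(A, B, tol=1e-12)
        s2 = blondel_similarity(7.3 * A, B, tol=1e-12)
        assert np.max(np.abs(s1.S - s2.S)) < 1e-9

    def test_max_iter_reported(self):
        rng = np.random.default_rng(5)
        A, B = rng.random((4, 4)), rng.random((4, 4))
        sim = blondel_similarity(A, B, tol=0.0, max_iter=6)
        assert not sim.converged
        assert sim.iterations == 6


class TestThreshold:
    def _sim(self):
        rng = np.random.default_rng(6)
        A, B = rng.random((5, 5)), rng.random((5, 5))
        return blondel_similarity(A, B)

    def test_level_zero_identity(self):
        sim = self._sim()
        S, scores, sparsity = threshold_similarity(sim, 0.0)
        assert np.array_equal(S, sim.S)
        assert sparsity == 1.0

    def test_level_one_keeps_at_most_largest(self):
        sim = self._sim()
        S, _, _ = threshold_similarity(sim, 1.0)
        assert np.count_nonzero(S) <= 1

    def test_mask_matches_direct_comparison(self):
        sim = self._sim()
        S, _, sparsity = threshold_similarity(sim, 0.1)
        expect = np.where(sim.S >= 0.1, sim.S, 0.0)
        assert np.array_equal(S, expect)
        assert sparsity == np.count_nonzero(expect) / expect.size

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            threshold_similarity(self._sim(), 1.5)
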