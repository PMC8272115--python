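"""Clustering, size statistics, order parameter and shape descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from dpdmc import analysis
from dpdmc.analysis import (
    UndefinedStatisticsError,
    UnwrapAmbiguityError,
    detect_cores,
    find_aggregates,
    gyration_shape,
    order_parameter,
    size_statistics,
    unwrap_cluster,
)

from conftest import brute_force_clusters


def cluster_sets(agg):
    return {frozenset(c.tolist()) for c in agg.clusters}


class TestFindAggregates:
    def test_pair_below_cutoff_merges(self):
        pos = np.array([[2.0, 2, 2], [3.4, 2, 2]])
        agg = find_aggregates(pos, 10.0)
        assert agg.n_clusters == 1 and len(agg.largest()) == 2

    def test_pair_above_cutoff_stays_separate(self):
        pos = np.array([[2.0, 2, 2], [3.6, 2, 2]])
        assert find_aggregates(pos, 10.0).n_clusters == 2

    def test_neighbors_across_periodic_face(self):
        pos = np.array([[0.2, 5, 5], [9.8, 5, 5]])
        assert find_aggregates(pos, 10.0).n_clusters == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 8.0, (50, 3))
        agg = find_aggregates(pos, 8.0)
        assert cluster_sets(agg) == set(brute_force_clusters(pos, 8.0, 1.5))

    def test_empty_subset(self):
        agg = find_aggregates(np.empty((0, 3)), 10.0)
        assert agg.n_clusters == 0

    def test_subset_restricts_clustering(self):
        pos = np.array([[1.0, 1, 1], [1.5, 1, 1], [2.0, 1, 1]])
        agg = find_aggregates(pos, 10.0, subset=np.array([0, 2]))
        assert agg.n_clusters == 1  # 0 and 2 are 1.0 apart
        assert cluster_sets(agg) == {frozenset({0, 2})}

    def test_partition_covers_subset(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 6.0, (80, 3))
        agg = find_aggregates(pos, 6.0)
        assert sorted(np.concatenate(agg.clusters)) == list(range(80))

    def test_invariant_under_ordering_and_translation(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, 8.0, (60, 3))
        base = cluster_sets(find_aggregates(pos, 8.0))
        perm = rng.permutation(60)
        inv = np.argsort(perm)
        permuted = cluster_sets(find_aggregates(pos[perm], 8.0))
        remapped = {frozenset(int(inv[i]) for i in c) for c in base}
        assert permuted == remapped
        shifted = (pos + np.array([3.7, -2.1, 5.9])) % 8.0
        assert cluster_sets(find_aggregates(shifted, 8.0)) == base


class TestSizeStatistics:
    @pytest.mark.parametrize("sizes, xn, xw, p", [
        ([10, 10, 10], 10, 10, 1.0),
        ([10, 30], 20, 25, 1.25),
        ([42], 42, 42, 1.0),
    ])
    def test_closed_form_examples(self, sizes, xn, xw, p):
        s = size_statistics(np.array(sizes))
        assert s.Xn == pytest.approx(xn)
        assert s.Xw == pytest.approx(xw)
        assert s.P == pytest.approx(p)

    def test_empty_set_is_undefined(self):
        with pytest.raises(UndefinedStatisticsError):
            size_statistics(np.array([], dtype=int))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=1000), min_size=1,
                    max_size=30), st.integers(min_value=1, max_value=50))
    def test_scaling_and_ordering_invariants(self, sizes, k):
        s = size_statistics(np.array(sizes))
        assert s.Xw >= s.Xn - 1e-12
        assert s.P >= 1.0 - 1e-12
        scaled = size_statistics(np.array(sizes) * k)
        assert scaled.Xn == pytest.approx(k * s.Xn)
        assert scaled.Xw == pytest.approx(k * s.Xw)
        assert scaled.P == pytest.approx(s.P)
        shuffled = size_statistics(np.array(sorted(sizes, reverse=True)))
        assert shuffled.P == pytest.approx(s.P)


class TestOrderParameter:
    def test_segregated_slab_gives_unity(self):
        z = np.concatenate([np.linspace(0.5, 4.5, 40),
                            np.linspace(5.5, 9.5, 40)])
        pos = np.column_stack([np.full(80, 5.0), np.full(80, 5.0), z])
        res = order_parameter(pos, 10.0, np.arange(40), np.arange(40, 80),
                              n_slices=10)
        assert res.phi == pytest.approx(1.0)

    def test_uniform_mixture_gives_zero(self):
        z = np.repeat(np.arange(10) + 0.5, 2)
        pos = np.column_stack([np.full(20, 1.0), np.full(20, 1.0), z])
        res = order_parameter(pos, 10.0, np.arange(0, 20, 2),
                              np.arange(1, 20, 2), n_slices=10)
        assert res.phi == pytest.approx(0.0)

    def test_four_slice_toy_layout(self):
        # per-slice (A, B) counts (10,0),(5,5),(0,10),(0,0) plus 10 W each;
        # fractions .5/.0, .25/.25, .0/.5, 0/0 -> phi = (0.5+0+0.5+0)/4
        counts = [(10, 0), (5, 5), (0, 10), (0, 0)]
        pos, a_idx, b_idx = [], [], []
        k = 0
        for s, (na, nb) in enumerate(counts):
            zc = s + 0.5
            for _ in range(na):
                pos.append([1.0, 1.0, zc]); a_idx.append(k); k += 1
            for _ in range(nb):
                pos.append([2.0, 1.0, zc]); b_idx.append(k); k += 1
            for _ in range(10):
                pos.append([3.0, 1.0, zc]); k += 1
        res = order_parameter(np.array(pos), 4.0, np.array(a_idx),
                              np.array(b_idx), n_slices=4)
        assert res.phi == pytest.approx(0.25)
        np.testing.assert_allclose(res.phi_a, [0.5, 0.25, 0.0, 0.0])
        np.testing.assert_allclose(res.phi_b, [0.0, 0.25, 0.5, 0.0])

    def test_default_slice_count_is_one_per_cutoff_radius(self):
        pos = np.full((5, 3), 2.0)
        res = order_parameter(pos, 17.0, np.arange(5),
                              np.empty(0, dtype=int))
        assert res.n_slices == 17

    def test_fraction_bounds(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 12.0, (300, 3))
        res = order_parameter(pos, 12.0, np.arange(100),
                              np.arange(100, 200))
        assert 0.0 <= res.phi <= 1.0
        assert (res.phi_a >= 0).all() and (res.phi_a <= 1).all()


class TestGyrationShape:
    def test_collinear_rod_has_delta_one(self):
        pos = np.column_stack([np.zeros(50), np.zeros(50),
                               np.linspace(0, 10, 50)])
        d = gyration_shape(pos, unwrapped=True)
        assert d.delta == pytest.approx(1.0, abs=1e-12)
        assert d.lam2_sq == pytest.approx(0.0, abs=1e-12)

    def test_flat_disk_has_delta_quarter(self):
        ang = 2 * np.pi * np.arange(12) / 12
        rings = [np.column_stack([r * np.cos(ang), r * np.sin(ang),
                                  np.zeros(12)]) for r in (1.0, 2.0, 3.0)]
        d = gyration_shape(np.vstack(rings), unwrapped=True)
        assert d.delta == pytest.approx(0.25, abs=1e-12)

    def test_uniform_ball_is_spherical(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(4000, 3))
        pts = pts / np.linalg.norm(pts, axis=1)[:, None]
        pts *= rng.uniform(0, 1, 4000)[:, None] ** (1 / 3) * 3.0
        d = gyration_shape(pts, unwrapped=True)
        assert d.delta == pytest.approx(0.0, abs=0.01)

    def test_rotation_and_translation_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(200, 3)) * np.array([3.0, 1.0, 0.5])
        base = gyration_shape(pts, unwrapped=True)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).apply(pts)
        moved = gyration_shape(rot + np.array([5.0, -2.0, 1.0]),
                               unwrapped=True)
        assert moved.delta == pytest.approx(base.delta, rel=1e-9)
        assert moved.rg_sq == pytest.approx(base.rg_sq, rel=1e-9)

    def test_cluster_split_by_periodic_boundary_is_unwrapped(self):
        rng = np.random.default_rng(3)
        blob = rng.normal(size=(400, 3))
        blob = 2.0 * blob / np.linalg.norm(blob, axis=1)[:, None]
        blob *= rng.uniform(0, 1, 400)[:, None] ** (1 / 3)  # dense ball r=2
        box = 12.0
        centered = gyration_shape(blob + 6.0, box_edge=box)
        split = gyration_shape((blob + 0.2) % box, box_edge=box)
        assert split.delta == pytest.approx(centered.delta, rel=1e-6)
        assert split.rg_sq == pytest.approx(centered.rg_sq, rel=1e-6)

    def test_percolating_ring_raises(self):
        # beads 1.0 apart around the full periodic circumference
        box = 10.0
        z = np.arange(0, box, 1.0)
        pos = np.column_stack([np.full_like(z, 5.0), np.full_like(z, 5.0), z])
        with pytest.raises(UnwrapAmbiguityError):
            unwrap_cluster(pos, box)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            gyration_shape(np.empty((0, 3)), unwrapped=True)


class TestDetectCores:
    def test_disjoint_spheres_inside_one_aggregate(self):
        rng = np.random.default_rng(0)
        centers = np.array([[6.0, 6, 6], [12.0, 6, 6], [9.0, 11, 6],
                            [6.0, 6, 11], [12.0, 6, 11]])
        core_pts = np.vstack([c + rng.normal(scale=0.4, size=(30, 3))
                              for c in centers])
        # bridge beads chain the core centers into one aggregate
        segs = [np.linspace(centers[k], centers[k + 1], 15)
                for k in range(len(centers) - 1)]
        pos = np.vstack([core_pts] + segs)
        box = 18.0
        agg = analysis.find_aggregates(pos, box)
        assert agg.n_clusters == 1
        cores = detect_cores(pos, box, agg, np.arange(len(core_pts)))
        assert len(cores[0]) == 5

    def test_aggregate_without_core_species(self):
        pos = np.array([[2.0, 2, 2], [2.5, 2, 2]])
        agg = analysis.find_aggregates(pos, 10.0)
        cores = detect_cores(pos, 10.0, agg, np.empty(0, dtype=int))
        assert cores == [[]]

    @pytest.mark.parametrize("seed", [5, 6])
    def test_matches_restricted_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 7.0, (60, 3))
        core_idx = np.arange(0, 60, 2)
        agg = analysis.find_aggregates(pos, 7.0)
        per_agg = detect_cores(pos, 7.0, agg, core_idx)
        got = {frozenset(core.tolist())
               for cores in per_agg for core in cores}
        # oracle: cluster core beads of each aggregate by transitive closure
        expected = set()
        for members in agg.clusters:
            sub = np.array([i for i in members if i % 2 == 0])
            if len(sub) == 0:
                continue
            for comp in brute_force_clusters(pos[sub], 7.0, 1.5):
                expected.add(frozenset(int(sub[i]) for i in comp))
        assert got == expected
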