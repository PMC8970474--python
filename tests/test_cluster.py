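"""Nanocluster detection against an exhaustive density-reachability oracle,
longest-axis geometry, size histograms, ring fitting, bracelet scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from psdnano import cluster as clu


def table_from(points):
    pts = np.asarray(points, dtype=float)
    return pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1]})


def dbscan_oracle(points: np.ndarray, eps: float, min_points: int) -> np.ndarray:
    """Exhaustive density-reachability closure, independent of sklearn.

    Core points are those with >= min_points neighbours within eps
    (counting themselves).  Clusters are connected components of the core
    graph, seeded in input order; unlabelled non-core points within eps of
    a component's core points join the earliest component that reaches
    them.  The rest are noise (-1).
    """
    n = len(points)
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    adj = d2 <= eps ** 2
    core = adj.sum(1) >= min_points
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        # density-reachability closure from seed i over core points
        comp = {i}
        frontier = [i]
        while frontier:
            j = frontier.pop()
            for k in np.flatnonzero(adj[j] & core):
                if k not in comp:
                    comp.add(int(k))
                    frontier.append(int(k))
        members = sorted(comp)
        labels[members] = cid
        for j in members:  # attach unclaimed border points
            for k in np.flatnonzero(adj[j]):
                if labels[k] == -1 and not core[k]:
                    labels[k] = cid
        cid += 1
    return labels


class TestDBSCAN:
    def test_five_coincident_points_form_one_cluster(self):
        cs = clu.detect_clusters_dbscan(table_from([[0, 0]] * 5))
        assert len(cs) == 1
        assert (cs.labels == 0).all()

    def test_four_coincident_points_are_noise(self):
        cs = clu.detect_clusters_dbscan(table_from([[0, 0]] * 4))
        assert len(cs) == 0
        assert (cs.labels == -1).all()

    def test_empty_table(self):
        cs = clu.detect_clusters_dbscan(pd.DataFrame(columns=["x", "y", "uncertainty"]))
        assert len(cs) == 0 and len(cs.labels) == 0

    def test_partition_matches_reachability_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(40):
            n = int(rng.integers(20, 301))
            pts = rng.uniform(0, 1000, size=(n, 2))
            cs = clu.detect_clusters_dbscan(table_from(pts))
            expected = dbscan_oracle(pts, 20.0, 5)
            np.testing.assert_array_equal(cs.labels, expected)

    def test_oracle_equivalence_on_clustered_data(self, clean_geometry):
        from psdnano import simulate
        tables, _ = simulate.simulate_bracelet_synapse(clean_geometry, seed=9)
        pts = tables[simulate.SPECIES_A][["x", "y"]].to_numpy()[:300]
        cs = clu.detect_clusters_dbscan(table_from(pts))
        np.testing.assert_array_equal(cs.labels, dbscan_oracle(pts, 20.0, 5))


class TestLongestAxis:
    def test_single_point_is_zero(self):
        assert clu.cluster_longest_axis(np.array([[1.0, 2.0]])) == 0.0

    def test_two_points(self):
        assert clu.cluster_longest_axis(np.array([[0, 0], [0, 37.0]])) == pytest.approx(37.0)

    def test_matches_brute_force(self, rng):
        pts = rng.normal(size=(50, 2)) * 30
        brute = max(
            math.dist(p, q) for i, p in enumerate(pts) for q in pts[i + 1:]
        )
        assert clu.cluster_longest_axis(pts) == pytest.approx(brute)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(-1e4, 1e4), st.floats(0, 2 * math.pi))
    def test_translation_and_rotation_invariant(self, seed, shift, angle):
        pts = np.random.default_rng(seed).normal(size=(12, 2)) * 40
        rot = np.array([[math.cos(angle), -math.sin(angle)],
                        [math.sin(angle), math.cos(angle)]])
        moved = pts @ rot.T + shift
        assert clu.cluster_longest_axis(moved) == pytest.approx(
            clu.cluster_longest_axis(pts), rel=1e-9, abs=1e-6)


class TestSizeHistogram:
    def test_overflow_pooling(self):
        edges, counts = clu.size_histogram(np.array([10.0, 20.0, 431.0]), 15.0, 400.0)
        assert counts[0] == 1 and counts[1] == 1 and counts[-1] == 1
        assert counts.sum() == 3
        assert edges[-1] == np.inf

    def test_empty_input(self):
        _, counts = clu.size_histogram(np.array([]), 15.0, 400.0)
        assert counts.sum() == 0

    def test_count_conservation(self, rng):
        vals = rng.gamma(2.0, 100.0, size=500)
        _, counts = clu.size_histogram(vals, 15.0, 400.0)
        assert counts.sum() == 500

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            clu.size_histogram(np.array([-1.0]), 15.0)


class TestRingEstimate:
    def test_exact_circle_recovered(self):
        ang = np.linspace(0, 2 * math.pi, 6, endpoint=False)
        pts = 400.0 * np.column_stack([np.cos(ang), np.sin(ang)]) + [120.0, -40.0]
        est = clu.estimate_ring_diameter(pts)
        assert est.defined
        assert est.diameter == pytest.approx(800.0, abs=1e-9)
        assert est.residual == pytest.approx(0.0, abs=1e-9)
        assert est.centre == pytest.approx((120.0, -40.0))

    def test_undersupported_is_undefined(self):
        est = clu.estimate_ring_diameter(np.array([[0, 0], [100, 0]]))
        assert not est.defined and est.diameter is None

    def test_collinear_is_undefined(self):
        est = clu.estimate_ring_diameter(np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]]))
        assert not est.defined

    def test_unbiased_on_noiseless_circles(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 12))
            ang = rng.uniform(0, 2 * math.pi, n)
            if np.ptp(ang) < 0.5:  # nearly collinear support is flagged, not fitted
                continue
            r = rng.uniform(100, 600)
            pts = r * np.column_stack([np.cos(ang), np.sin(ang)])
            est = clu.estimate_ring_diameter(pts)
            if est.defined:
                assert est.diameter == pytest.approx(2 * r, rel=1e-6)


class TestBraceletScore:
    def test_perfect_ring_scores_one(self):
        ang = np.linspace(0, 2 * math.pi, 8, endpoint=False) + 0.1
        pts = 400.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        res = clu.classify_bracelet(pts, (0.0, 0.0))
        assert res.score == pytest.approx(1.0)
        assert res.is_bracelet

    def test_central_clusters_are_not_a_bracelet(self):
        pts = np.zeros((5, 2))
        res = clu.classify_bracelet(pts, (0.0, 0.0))
        assert not res.is_bracelet
        assert res.central_violation_ratio == 1.0

    def test_no_clusters_scores_zero(self):
        res = clu.classify_bracelet(np.empty((0, 2)), (0.0, 0.0))
        assert res.score == 0.0 and not res.is_bracelet


class TestPrevalenceRecovery:
    def test_recovered_prevalence_tracks_generator_truth(self):
        """Mixture at 65% bracelet probability: classified prevalence over
        200 synapses within +-0.07 of the generated truth."""
        from psdnano import locio, simulate
        geometry = simulate.BraceletGeometry()
        calls, truths = [], []
        for i in range(200):
            tables, truth = simulate.simulate_bracelet_synapse(geometry, seed=5000 + i)
            centroids = []
            for species in (simulate.SPECIES_A, simulate.SPECIES_B):
                filtered = locio.filter_by_precision(tables[species])
                centroids.append(clu.detect_clusters_dbscan(filtered))
            pts = clu.combined_peripheral_centroids(*centroids)
            calls.append(clu.classify_bracelet(pts, truth.centre).is_bracelet)
            truths.append(truth.bracelet)
        assert abs(np.mean(calls) - np.mean(truths)) <= 0.07
        assert np.mean(truths) == pytest.approx(0.65, abs=0.08)
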