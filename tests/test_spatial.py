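"""Radial profiles, NN distances, CSR and toroidal-shift null models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psdnano import spatial

ISO = (100.0, 100.0, 100.0)


class TestRadialProfile:
    def test_point_source_peaks_in_first_bin(self):
        stack = np.zeros((20, 20, 20))
        stack[10, 10, 10] = 100.0
        centre = (np.array([10, 10, 10]) + 0.5) * 100.0
        prof = spatial.normalize_profile(
            spatial.radial_profile_3d(stack, centre, ISO,
                                      spatial.RadialProfileParams(100.0, 900.0)))
        assert prof[0] == 1.0
        assert prof[-1] == pytest.approx(0.0, abs=1e-6)

    def test_shell_maximum_in_matching_bin(self):
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in (24, 24, 24)), indexing="ij")
        centre_vox = np.array([12, 12, 12])
        dist = 100.0 * np.sqrt(((zz - centre_vox[0])) ** 2 + ((yy - centre_vox[1])) ** 2
                               + ((xx - centre_vox[2])) ** 2)
        stack = np.where(np.abs(dist - 250.0) < 60.0, 50.0, 0.0)
        centre = (centre_vox + 0.5) * 100.0
        params = spatial.RadialProfileParams(bin_width=100.0, max_radius=1000.0)
        prof = spatial.radial_profile_3d(stack, centre, ISO, params)
        assert np.nanargmax(prof) == 2  # bin [200, 300) contains 250

    def test_constant_stack_normalises_to_zero_with_warning(self, caplog):
        stack = np.full((10, 10, 10), 7.0)
        centre = np.array([500.0, 500.0, 500.0])
        prof = spatial.radial_profile_3d(stack, centre, ISO,
                                         spatial.RadialProfileParams(100.0, 400.0))
        with caplog.at_level("WARNING"):
            normed = spatial.normalize_profile(prof)
        assert np.all(normed == 0.0)
        assert any("degenerate" in r.message for r in caplog.records)

    def test_border_truncated_shells_are_nan(self):
        stack = np.ones((10, 10, 10))
        centre = np.array([150.0, 150.0, 150.0])  # 150 nm from the border
        prof = spatial.radial_profile_3d(stack, centre, ISO,
                                         spatial.RadialProfileParams(100.0, 800.0))
        assert np.isfinite(prof[0])
        assert np.isnan(prof[3:]).all()


class TestNNDistances:
    def test_nearest_of_two_targets(self):
        d = spatial.nn_distances(np.array([[0.0, 0, 0]]),
                                 np.array([[300.0, 0, 0], [500.0, 0, 0]]))
        assert d == pytest.approx([300.0])

    def test_tangent_spheres_have_zero_surface_gap(self):
        d = spatial.nn_distances(
            np.array([[0.0, 0, 0]]), np.array([[250.0, 0, 0]]), mode="surface",
            from_radii=np.array([100.0]), to_radii=np.array([150.0]))
        assert d == pytest.approx([0.0])

    def test_surface_matches_brute_force(self, rng):
        a = rng.uniform(0, 1000, (8, 3))
        b = rng.uniform(0, 1000, (11, 3))
        ra = rng.uniform(10, 120, 8)
        rb = rng.uniform(10, 120, 11)
        got = spatial.nn_distances(a, b, mode="surface", from_radii=ra, to_radii=rb)
        for i in range(8):
            brute = min(
                max(0.0, math.dist(a[i], b[j]) - ra[i] - rb[j]) for j in range(11)
            )
            assert got[i] == pytest.approx(brute)

    def test_direction_matters_but_not_for_singletons(self, rng):
        a = rng.uniform(0, 500, (5, 3))
        b = rng.uniform(0, 500, (9, 3))
        ab = spatial.nn_distances(a, b)
        ba = spatial.nn_distances(b, a)
        assert len(ab) == 5 and len(ba) == 9
        a1, b1 = a[:1], b[:1]
        assert spatial.nn_distances(a1, b1)[0] == pytest.approx(
            spatial.nn_distances(b1, a1)[0])

    def test_surface_never_exceeds_centre_distance(self, rng):
        a = rng.uniform(0, 800, (20, 3))
        b = rng.uniform(0, 800, (20, 3))
        ra = rng.uniform(0, 100, 20)
        rb = rng.uniform(0, 100, 20)
        surf = spatial.nn_distances(a, b, mode="surface", from_radii=ra, to_radii=rb)
        cent = spatial.nn_distances(a, b, mode="centre")
        assert np.all(surf <= cent + 1e-9)

    def test_empty_target_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            spatial.nn_distances(np.zeros((1, 3)), np.empty((0, 3)))


class TestCSRNull:
    def test_singleton_distances_bounded_by_sphere_diameter(self):
        env = spatial.csr_null([(1, 1)] * 50, None, np.arange(0, 900, 50.0), seed=0)
        beyond = env.null_mean[env.bin_edges[:-1] >= 800.0]
        assert np.all(beyond == 0.0)

    def test_mean_nn_distance_matches_naive_sampler(self):
        # independent oracle: naive paired sampling, fresh formulas
        def naive_mean(n, seed):
            r = np.random.default_rng(seed)
            radius = 400.0
            costh = 1 - 2 * r.random(n)
            sinth = np.sqrt(1 - costh ** 2)
            phi = r.uniform(0, 2 * math.pi, n)
            rad = radius * r.random(n) ** (1 / 3)
            a = np.column_stack([rad * sinth * np.cos(phi), rad * sinth * np.sin(phi),
                                 rad * costh])
            costh2 = 1 - 2 * r.random(n)
            sinth2 = np.sqrt(1 - costh2 ** 2)
            phi2 = r.uniform(0, 2 * math.pi, n)
            b = np.column_stack([radius * sinth2 * np.cos(phi2),
                                 radius * sinth2 * np.sin(phi2), radius * costh2])
            return np.linalg.norm(a - b, axis=1).mean()

        rng = np.random.default_rng(1)
        n = 4000
        a = spatial.sample_in_sphere(rng, n, 400.0)
        b = spatial.sample_on_sphere(rng, n, 400.0)
        impl = np.linalg.norm(a - b, axis=1).mean()
        assert impl == pytest.approx(naive_mean(20000, 2), rel=0.01)

    def test_envelope_ordering(self):
        env = spatial.csr_null([(3, 4)] * 20, None, np.arange(0, 900, 50.0), seed=3)
        assert np.all(env.lower <= env.null_mean + 1e-12)
        assert np.all(env.null_mean <= env.upper + 1e-12)
        assert np.all(env.null_min <= env.null_max)

    def test_radius_exceeding_sphere_warns(self, caplog):
        radii = ([500.0], [10.0])
        with caplog.at_level("WARNING"):
            spatial.csr_null([(1, 1)], [radii], np.arange(0, 900, 50.0),
                             mode="surface", seed=0)
        assert any("exceeds" in r.message for r in caplog.records)


class TestToroidalShift:
    def test_wrap_at_field_edge(self):
        out = spatial.toroidal_shift(
            np.array([[990.0, 0.0]]), (np.array([0.0, 0.0]), np.array([1000.0, 1000.0])),
            shift=20.0, direction=np.array([1.0, 0.0]))
        assert out[0] == pytest.approx([10.0, 0.0])

    def test_zero_magnitude_is_identity(self):
        pts = np.array([[10.0, 20.0], [990.0, 500.0]])
        out = spatial.toroidal_shift(
            pts, (np.zeros(2), np.full(2, 1000.0)), shift=0.0,
            direction=np.array([0.3, 0.7]))
        np.testing.assert_allclose(out, pts)

    def test_null_requires_positive_shift(self):
        with pytest.raises(ValueError, match="shift"):
            spatial.toroidal_shift_null(np.zeros((1, 2)), np.zeros((1, 2)),
                                        (np.zeros(2), np.ones(2)), shift=0.0)

    def test_planted_offset_pairs_lose_first_bin_after_shift(self, rng):
        # pairs at 10 nm offsets: observed first-bin count collapses under the null
        base = rng.uniform(100, 1900, (40, 2))
        offset_dir = rng.normal(size=(40, 2))
        offset_dir /= np.linalg.norm(offset_dir, axis=1, keepdims=True)
        partner = base + 10.0 * offset_dir
        bounds = (np.zeros(2), np.full(2, 2000.0))
        edges = np.arange(0.0, 300.0, 15.0)
        obs = np.histogram(spatial.nn_distances(base, partner), bins=edges)[0]
        null = np.histogram(
            spatial.toroidal_shift_null(base, partner, bounds, shift=20.0, seed=5),
            bins=edges)[0]
        assert null[0] < obs[0]


class TestAggregation:
    def test_identical_histograms_zero_sem(self):
        h = np.array([1.0, 2.0, 3.0])
        mean, sem = spatial.aggregate_histograms([h, h, h, h], [0, 0, 1, 1])
        np.testing.assert_allclose(mean, h)
        np.testing.assert_allclose(sem, 0.0)

    def test_single_experiment_flags_sem(self):
        mean, sem = spatial.aggregate_histograms([np.ones(3)], ["e1"])
        assert np.isnan(sem).all()

    def test_matches_nested_mean_oracle(self, rng):
        hists = [rng.random(6) for _ in range(9)]
        eids = [0, 0, 0, 1, 1, 2, 2, 2, 2]
        mean, sem = spatial.aggregate_histograms(hists, eids)
        # hand-rolled two-level arithmetic
        groups = {}
        for h, e in zip(hists, eids):
            groups.setdefault(e, []).append(h)
        per_exp = np.array([np.mean(v, axis=0) for v in groups.values()])
        np.testing.assert_allclose(mean, per_exp.mean(axis=0))
        np.testing.assert_allclose(sem, per_exp.std(axis=0, ddof=1) / math.sqrt(3))

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            spatial.aggregate_histograms([np.ones(3), np.ones(4)], [0, 1])

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10 ** 6))
    def test_mean_invariant_to_image_order(self, seed):
        r = np.random.default_rng(seed)
        hists = [r.random(4) for _ in range(6)]
        eids = [0, 1, 2, 0, 1, 2]
        mean1, _ = spatial.aggregate_histograms(hists, eids)
        order = r.permutation(6)
        mean2, _ = spatial.aggregate_histograms([hists[i] for i in order],
                                                [eids[i] for i in order])
        np.testing.assert_allclose(mean1, mean2)
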