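"""Fiber geometry: resampling, length, d_ME and its cutoff variant, centroids."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tractokit import (EXCEEDS, Tractogram, bundle_centroid, dme, dme_matrix,
                       dme_to_many, dme_with_cutoff, fiber_length, resample)
from conftest import random_polyline


def dme_bruteforce(a, b):
    """Literal double-loop evaluation of the max-corresponding-point distance,
    minimized over the direct and the fully reversed order of b."""
    n = len(a)

    def pointdist(p, q):
        dx, dy, dz = p[0] - q[0], p[1] - q[1], p[2] - q[2]
        return math.sqrt(dx * dx + dy * dy + dz * dz)

    direct = rev = 0.0
    for i in range(n):
        direct = max(direct, pointdist(a[i], b[i]))
        rev = max(rev, pointdist(a[i], b[n - 1 - i]))
    return min(direct, rev)


class TestDme:
    def test_matches_bruteforce_on_random_pairs(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 40))
            a = random_polyline(rng, n)
            b = random_polyline(rng, n)
            assert dme(a, b) == pytest.approx(dme_bruteforce(a, b), abs=0)

    def test_identity_and_reversal_are_zero(self, rng):
        f = random_polyline(rng, 21)
        assert dme(f, f) == 0.0
        assert dme(f, f[::-1]) == 0.0

    def test_translation(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        b = a + [0, 1, 0]
        # reverse branch gives sqrt(5) >= 1, so the direct branch wins
        assert dme(a, b) == pytest.approx(1.0)

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(50):
            a, b = random_polyline(rng, 15), random_polyline(rng, 15)
            d = dme(a, b)
            assert d >= 0
            assert d == pytest.approx(dme(b, a), abs=0)

    def test_rigid_motion_invariance(self, rng):
        a, b = random_polyline(rng, 21), random_polyline(rng, 21)
        d0 = dme(a, b)
        for _ in range(10):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-100, 100, 3)
            assert dme(a @ R.T + t, b @ R.T + t) == pytest.approx(d0, abs=1e-9)

    def test_unequal_point_counts_rejected(self, rng):
        with pytest.raises(ValueError, match="resample"):
            dme(random_polyline(rng, 10), random_polyline(rng, 12))

    def test_matrix_and_to_many_agree_with_scalar(self, rng):
        A = np.stack([random_polyline(rng, 12) for _ in range(8)])
        B = np.stack([random_polyline(rng, 12) for _ in range(5)])
        D = dme_matrix(A, B)
        for i in range(8):
            np.testing.assert_allclose(dme_to_many(A[i], B), D[i], atol=1e-12)
            for j in range(5):
                assert D[i, j] == pytest.approx(dme(A[i], B[j]), abs=1e-12)


class TestDmeWithCutoff:
    def test_identical_fibers_zero(self, rng):
        f = random_polyline(rng, 21)
        assert dme_with_cutoff(f, f, 0.001) == 0.0

    def test_parallel_far_fibers_exceed(self):
        a = np.array([[0, 0, 0], [10, 0, 0]], float)
        assert dme_with_cutoff(a, a + [0, 10, 0], 6.0) is EXCEEDS

    def test_equivalence_with_dme(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 30))
            a, b = random_polyline(rng, n), random_polyline(rng, n)
            cutoff = float(rng.uniform(1, 60))
            ref = dme(a, b)
            got = dme_with_cutoff(a, b, cutoff)
            if ref > cutoff:
                assert got is EXCEEDS
            else:
                assert got == pytest.approx(ref, abs=1e-12)
                assert got <= cutoff


class TestResample:
    def test_straight_segment_21_points(self):
        f = np.array([[0, 0, 0], [10, 0, 0]], float)
        out = resample(f, 21)
        np.testing.assert_allclose(out[:, 0], np.arange(21) * 0.5, atol=1e-12)
        np.testing.assert_allclose(out[:, 1:], 0)

    def test_idempotent_on_equidistant_input(self):
        f = np.column_stack([np.linspace(0, 10, 11), np.zeros(11), np.zeros(11)])
        np.testing.assert_allclose(resample(f, 11), f, atol=1e-9)

    @staticmethod
    def arc_positions(f, out):
        """Arc-length position of each output point along the input polyline,
        computed by an independent segment-walking oracle."""
        seg = np.linalg.norm(np.diff(f, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        pos = []
        for p in out:
            # locate p on (or next to) one of the input segments
            best = None
            for k in range(len(f) - 1):
                d = f[k + 1] - f[k]
                L2 = d @ d
                t = 0.0 if L2 == 0 else np.clip((p - f[k]) @ d / L2, 0, 1)
                q = f[k] + t * d
                err = np.linalg.norm(p - q)
                if best is None or err < best[0]:
                    best = (err, cum[k] + t * seg[k])
            assert best[0] <= 1e-8  # every output point lies on the polyline
            pos.append(best[1])
        return np.asarray(pos)

    def test_equidistant_arc_steps_property(self, rng):
        """Consecutive resampled points are equidistant along the input
        polyline's arc length (the chord positions are interpolated within
        segments), with spacing L/(npoints-1)."""
        for _ in range(25):
            f = random_polyline(rng, 50)
            out = resample(f, 21)
            pos = self.arc_positions(f, out)
            steps = np.diff(pos)
            spacing = pos[-1] / 20
            assert np.all(np.abs(steps - spacing) <= 1e-6 * spacing)

    def test_endpoints_preserved_exactly(self, rng):
        f = random_polyline(rng, 30)
        out = resample(f, 13)
        assert np.array_equal(out[0], f[0]) and np.array_equal(out[-1], f[-1])

    def test_length_converges_monotonically(self, rng):
        f = random_polyline(rng, 40)
        lengths = [fiber_length(resample(f, n)) for n in (5, 10, 20, 40, 80)]
        assert all(b >= a - 1e-9 for a, b in zip(lengths, lengths[1:]))
        assert lengths[-1] <= fiber_length(f) + 1e-9

    def test_zero_length_segments_tolerated(self):
        f = np.array([[0, 0, 0], [0, 0, 0], [10, 0, 0]], float)
        out = resample(f, 5)
        np.testing.assert_allclose(out[:, 0], [0, 2.5, 5, 7.5, 10], atol=1e-9)

    def test_npoints_below_two_rejected(self, rng):
        with pytest.raises(ValueError):
            resample(random_polyline(rng, 10), 1)


class TestFiberLength:
    def test_three_four_five(self):
        assert fiber_length(np.array([[0, 0, 0], [3, 4, 0]], float)) == 5.0

    def test_closed_loop_positive(self):
        loop = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 0, 0]], float)
        assert fiber_length(loop) > 0

    def test_resampled_arc_length_within_one_percent(self):
        theta = np.linspace(0, np.pi / 2, 200)
        arc = np.column_stack([40 * np.cos(theta), 40 * np.sin(theta),
                               np.zeros_like(theta)])
        analytic = 40 * np.pi / 2
        assert fiber_length(resample(arc, 21)) == pytest.approx(analytic, rel=0.01)


class TestBundleCentroid:
    def test_single_fiber_is_itself(self, rng):
        f = random_polyline(rng, 21)
        np.testing.assert_allclose(bundle_centroid([f]), f)

    def test_reversed_duplicate_aligns(self, rng):
        f = random_polyline(rng, 21)
        np.testing.assert_allclose(bundle_centroid([f, f[::-1]]), f, atol=1e-12)

    def test_jittered_copies_recover_backbone(self):
        rng = np.random.default_rng(7)
        backbone = np.column_stack([np.linspace(0, 80, 21),
                                    np.zeros(21), np.zeros(21)])
        fibers = []
        for k in range(20):
            f = backbone + rng.normal(scale=0.5, size=backbone.shape)
            fibers.append(f[::-1] if k % 2 else f)
        cent = bundle_centroid(fibers)
        dev = np.linalg.norm(cent - backbone, axis=1).max()
        assert dev <= 0.5

    def test_medoid_mode_returns_a_member(self, rng):
        fibers = [random_polyline(rng, 15) for _ in range(7)]
        med = bundle_centroid(fibers, mode="medoid")
        assert any(np.array_equal(med, f) for f in fibers)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            bundle_centroid([])


class TestTractogram:
    def test_label_ranges_partition(self):
        fibers = [np.zeros((3, 3)) + i for i in range(6)]
        t = Tractogram(fibers=fibers, labels=[("a", 0), ("b", 4)])
        assert t.label_ranges() == [("a", 0, 4), ("b", 4, 6)]
        assert t.fiber_labels().tolist() == [0, 0, 0, 0, 1, 1]

    def test_bad_labels_rejected(self):
        fibers = [np.zeros((3, 3))] * 4
        with pytest.raises(ValueError):
            Tractogram(fibers=fibers, labels=[("a", 1)])
        with pytest.raises(ValueError):
            Tractogram(fibers=fibers, labels=[("a", 0), ("b", 9)])
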