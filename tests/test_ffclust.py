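"""Fast fiber clustering: the four stages against brute-force oracles, plus
pipeline-level partition/determinism/no-fusion properties."""

import numpy as np
import pytest

from tractokit import (BundleSpec, FFClustParams, PhantomSpec, Tractogram,
                       bundle_centroid, dme, dme_to_many, ffclust,
                       make_phantom, read_bundles_id, resample_stack,
                       stage1_point_kmeans, stage2_map, stage3_reassign,
                       stage4_merge)
from conftest import random_polyline


def small_params(**kw):
    """Parameters scaled to small unit-test tractograms."""
    defaults = dict(points=(0, 3, 10, 17, 20), ks=(8, 6, 6, 6, 8), seed=0)
    defaults.update(kw)
    return FFClustParams(**defaults)


@pytest.fixture(scope="module")
def ten_bundle_phantom():
    spec = PhantomSpec(bundles=[
        BundleSpec(kind="line",
                   params={"start": (35 * (k % 5), 40 * (k // 5), 0),
                           "direction": (0, 0.2 * (k % 3), 1), "length": 80},
                   n_fibers=200, jitter_sd=1.0, npoints_range=(15, 30))
        for k in range(10)], seed=21)
    return make_phantom(spec)


class TestStage1:
    def test_identical_fibers_constant_labeling(self, rng):
        f = random_polyline(rng, 21)
        t = Tractogram(fibers=[f.copy() for _ in range(5)])
        with pytest.warns(RuntimeWarning, match="clamping"):
            labeling = stage1_point_kmeans(t, small_params())
        for labels in labeling.values():
            assert len(set(labels.tolist())) == 1

    def test_two_far_groups_separate_at_every_point(self, rng):
        a = random_polyline(rng, 21)
        fibers = [a + rng.normal(scale=0.1, size=a.shape) for _ in range(20)]
        fibers += [a + 500.0 + rng.normal(scale=0.1, size=a.shape)
                   for _ in range(20)]
        t = Tractogram(fibers=fibers)
        labeling = stage1_point_kmeans(t, small_params(ks=(2, 2, 2, 2, 2)))
        truth = np.repeat([0, 1], 20)
        for labels in labeling.values():
            assert len(np.unique(labels[truth == 0])) == 1
            assert len(np.unique(labels[truth == 1])) == 1

    def test_defaults_match_published_values(self):
        p = FFClustParams()
        assert p.points == (0, 3, 10, 17, 20)
        assert p.ks == (300, 200, 200, 200, 300)
        assert p.assign_thr == 6.0 and p.join_thr == 6.0


class TestStage2:
    def test_identical_tuples_one_group(self):
        labeling = {0: np.zeros(5, int), 10: np.zeros(5, int), 20: np.zeros(5, int)}
        groups = stage2_map(labeling)
        assert list(groups.values()) == [[0, 1, 2, 3, 4]]

    def test_single_point_difference_splits(self):
        labeling = {0: np.array([1, 1]), 10: np.array([2, 3])}
        assert len(stage2_map(labeling)) == 2

    def test_matches_bruteforce_tuple_grouping(self, rng):
        labeling = {p: rng.integers(0, 4, size=200) for p in (0, 3, 10, 17, 20)}
        groups = stage2_map(labeling)
        pts = sorted(labeling)
        expected = {}
        for i in range(200):
            expected.setdefault(tuple(int(labeling[p][i]) for p in pts), []).append(i)
        assert groups == expected
        assert sorted(i for v in groups.values() for i in v) == list(range(200))


class TestStage3:
    def test_near_singleton_absorbed(self, rng):
        base = random_polyline(rng, 21)
        big = [base + rng.normal(scale=0.2, size=base.shape) for _ in range(100)]
        stray = base + 0.4
        t = Tractogram(fibers=big + [stray])
        clusters = {(0,) * 5: list(range(100)), (1,) * 5: [100]}
        out = stage3_reassign(clusters, t, small_params())
        assert out[(0,) * 5] == list(range(101))
        assert (1,) * 5 not in out

    def test_distant_singleton_unchanged(self, rng):
        base = random_polyline(rng, 21)
        big = [base + rng.normal(scale=0.2, size=base.shape) for _ in range(100)]
        t = Tractogram(fibers=big + [base + 500.0])
        clusters = {(0,) * 5: list(range(100)), (1,) * 5: [100]}
        out = stage3_reassign(clusters, t, small_params())
        assert out[(1,) * 5] == [100]

    def test_matches_bruteforce_nearest_large_centroid(self, rng):
        # three large clusters + planted strays
        bases = [random_polyline(rng, 21, scale=20) + 100 * k for k in range(3)]
        fibers, clusters = [], {}
        for k, base in enumerate(bases):
            mem = []
            for _ in range(20):
                mem.append(len(fibers))
                fibers.append(base + rng.normal(scale=0.3, size=base.shape))
            clusters[(k,) * 5] = mem
        strays = []
        for s in range(8):
            strays.append(len(fibers))
            fibers.append(bases[s % 3] + rng.normal(scale=3.0, size=(21, 3)))
            clusters[(10 + s,) * 5] = [strays[-1]]
        t = Tractogram(fibers=fibers)
        params = small_params(assign_thr=6.0)
        out = stage3_reassign(clusters, t, params)

        stack = resample_stack(t, 21)
        cents = {k: bundle_centroid(stack[clusters[(k,) * 5]]) for k in range(3)}
        for s in strays:
            d = {k: dme(stack[s], c) for k, c in cents.items()}
            kbest = min(d, key=lambda k: (d[k], k))
            if d[kbest] <= params.assign_thr:
                assert s in out[(kbest,) * 5]
            else:
                assert out[next(t_ for t_ in out if s in out[t_])] == [s]

    def test_large_clusters_never_shrink(self, rng):
        fibers = [random_polyline(rng, 21, scale=10) for _ in range(30)]
        t = Tractogram(fibers=fibers)
        clusters = {(0,) * 5: list(range(10)), (1,) * 5: list(range(10, 20)),
                    **{(2 + k,) * 5: [20 + k] for k in range(10)}}
        out = stage3_reassign(clusters, t, small_params())
        assert set(out[(0,) * 5]) >= set(range(10))
        assert set(out[(1,) * 5]) >= set(range(10, 20))
        assert sorted(i for v in out.values() for i in v) == list(range(30))


class TestStage4:
    def _clusters(self, rng, d_apart):
        base = random_polyline(rng, 21)
        other = base + [d_apart, 0.0, 0.0]
        fa = [base + rng.normal(scale=0.1, size=base.shape) for _ in range(10)]
        fb = [other + rng.normal(scale=0.1, size=base.shape) for _ in range(10)]
        t = Tractogram(fibers=fa + fb)
        clusters = {(0, 0, 7, 0, 0): list(range(10)),
                    (1, 1, 7, 1, 1): list(range(10, 20))}
        return t, clusters

    def test_same_central_label_close_merged(self, rng):
        t, clusters = self._clusters(rng, 3.0)
        res = stage4_merge(clusters, t, small_params())
        assert res.n_clusters() == 1

    def test_same_central_label_far_not_merged(self, rng):
        t, clusters = self._clusters(rng, 20.0)
        res = stage4_merge(clusters, t, small_params())
        assert res.n_clusters() == 2

    def test_different_central_label_not_merged(self, rng):
        t, clusters = self._clusters(rng, 3.0)
        clusters = {(0, 0, 7, 0, 0): clusters[(0, 0, 7, 0, 0)],
                    (1, 1, 8, 1, 1): clusters[(1, 1, 7, 1, 1)]}
        res = stage4_merge(clusters, t, small_params())
        assert res.n_clusters() == 2

    def test_enumeration_order_independent(self, rng):
        fibers = [random_polyline(rng, 21, scale=8) for _ in range(30)]
        t = Tractogram(fibers=fibers)
        # 10 clusters of 3 fibers; central label drawn from a small alphabet
        clusters = {}
        for c in range(10):
            key = (c, c, int(rng.integers(0, 3)), c, c)
            clusters[key] = [3 * c, 3 * c + 1, 3 * c + 2]
        items = list(clusters.items())
        res1 = stage4_merge(dict(items), t, small_params())
        rng.shuffle(items)
        res2 = stage4_merge(dict(items), t, small_params())
        part1 = sorted(tuple(v) for v in res1.clusters.values())
        part2 = sorted(tuple(v) for v in res2.clusters.values())
        assert part1 == part2


class TestPipeline:
    def test_all_identical_fibers_one_cluster(self, rng):
        f = random_polyline(rng, 21)
        t = Tractogram(fibers=[f.copy() for _ in range(12)])
        res = ffclust(t, small_params())
        assert res.n_clusters() == 1
        assert res.clusters[0] == list(range(12))

    def test_partition_after_every_stage(self, ten_bundle_phantom):
        t, labels, _ = ten_bundle_phantom
        params = FFClustParams(seed=3)
        stack = resample_stack(t, params.npoints)
        labeling = stage1_point_kmeans(t, params, stack)
        s2 = stage2_map(labeling)
        assert sorted(i for v in s2.values() for i in v) == list(range(len(t)))
        s3 = stage3_reassign(s2, t, params, stack)
        assert sorted(i for v in s3.values() for i in v) == list(range(len(t)))
        res = stage4_merge(s3, t, params, stack)
        assert sorted(i for v in res.clusters.values() for i in v) \
            == list(range(len(t)))
        assert np.all(res.labels >= 0)

    def test_reproducible_under_seed(self, ten_bundle_phantom):
        t, _, _ = ten_bundle_phantom
        r1 = ffclust(t, FFClustParams(seed=5))
        r2 = ffclust(t, FFClustParams(seed=5))
        assert np.array_equal(r1.labels, r2.labels)

    def test_never_fuses_separated_bundles(self, ten_bundle_phantom):
        """Clusters may split bundles but must not fuse bundles whose backbone
        separation exceeds twice the merge threshold."""
        t, labels, info = ten_bundle_phantom
        params = FFClustParams(seed=1)
        sep = info["separation_mm"]
        res = ffclust(t, params)
        for idx in res.clusters.values():
            present = sorted({int(labels[i]) for i in idx})
            for a in range(len(present)):
                for b in range(a + 1, len(present)):
                    assert sep[present[a], present[b]] <= 2 * params.join_thr

    def test_exports(self, tmp_path, rng):
        base = random_polyline(rng, 21)
        fibers = [base + rng.normal(scale=0.3, size=base.shape) for _ in range(25)]
        t = Tractogram(fibers=fibers)
        res = ffclust(t, small_params(ks=(3, 3, 3, 3, 3)), tmp_path)
        ids = read_bundles_id(tmp_path / "bundles_id.txt")
        assert sorted(i for v in ids.values() for i in v) == list(range(25))
        assert (tmp_path / "outputs" / "stage1_point_labels.txt").exists()
        assert len(list((tmp_path / "final_bundles").glob("*.bundles"))) \
            == res.n_clusters()

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            FFClustParams(points=(0, 3), ks=(10, 10, 10))
        with pytest.raises(ValueError):
            FFClustParams(points=(3, 0, 10, 17, 20), ks=(5,) * 5)
        with pytest.raises(ValueError):
            FFClustParams(assign_thr=-1.0)
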