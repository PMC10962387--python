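"""Fast fiber clustering: four-stage scalable intra-subject clustering.

Stage 1 runs an independent MiniBatch K-Means on the 3D coordinates of a few
selected points of every (resampled) fiber.  Stage 2 groups fibers whose label
tuples across the selected points are identical (map clustering).  Stage 3
reassigns fibers of small clusters to the nearest large cluster by d_ME to the
large clusters' centroids (direct and reversed order are both considered by
d_ME), when that distance is at most ``assign_thr``.  Stage 4 takes cluster
pairs whose Stage-1 label at the central selected point is equal, merges —
transitively, via union-find — those whose centroids are within ``join_thr``,
and recomputes centroids.

The method is designed as a pre-processing step for massive tractograms and
deliberately prefers oversegmentation over fusing differently shaped bundles.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import MiniBatchKMeans

from .geometry import (Tractogram, bundle_centroid, dme_matrix, dme_to_many,
                       resample_stack)
from .results import ClusteringResult, export_clustering

__all__ = ["FFClustParams", "stage1_point_kmeans", "stage2_map",
           "stage3_reassign", "stage4_merge", "ffclust"]

#: Stage-2 cluster mapping: label tuple -> ascending fiber indices.
MapClusters = dict[tuple[int, ...], list[int]]


@dataclass
class FFClustParams:
    """Parameters of the four-stage pipeline.

    ``points``: indices (into the resampled fiber) clustered in Stage 1,
    default ``(0, 3, 10, 17, 20)`` of a 21-point fiber.
    ``ks``: K-Means cluster counts per selected point, default
    ``(300, 200, 200, 200, 300)``.
    ``assign_thr`` / ``join_thr``: Stage-3 reassignment and Stage-4 merge
    distance thresholds in mm, both default 6.0.
    ``small_cluster_max_size``: clusters at or below this size are candidates
    for Stage-3 reassignment (default 5 — map clustering produces many
    near-singleton tuples that this stage exists to absorb).
    ``batch_size``/``max_iter``: MiniBatch K-Means controls (batch defaults to
    10% of the fiber count capped at 10,000).
    """

    points: tuple[int, ...] = (0, 3, 10, 17, 20)
    ks: tuple[int, ...] = (300, 200, 200, 200, 300)
    assign_thr: float = 6.0
    join_thr: float = 6.0
    small_cluster_max_size: int = 5
    seed: int = 0
    npoints: int = 21
    batch_size: int | None = None
    max_iter: int = 100
    centroid_mode: str = "mean"

    def __post_init__(self) -> None:
        self.points = tuple(int(p) for p in self.points)
        self.ks = tuple(int(k) for k in self.ks)
        if len(self.points) != len(self.ks):
            raise ValueError("points and ks must have equal length")
        if any(b <= a for a, b in zip(self.points, self.points[1:])):
            raise ValueError("points must be strictly increasing")
        if any(p < 0 or p >= self.npoints for p in self.points):
            raise ValueError(f"points must lie in [0, {self.npoints})")
        if self.assign_thr <= 0 or self.join_thr <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def central_point_position(self) -> int:
        """Index (within ``points``) of the central selected point: the middle
        entry of the list (point 10 of 21 under defaults)."""
        return len(self.points) // 2


def stage1_point_kmeans(tractogram: Tractogram, params: FFClustParams,
                        stack: np.ndarray | None = None) -> dict[int, np.ndarray]:
    """Independent MiniBatch K-Means per selected point.

    Returns ``{point_index: labels}`` with one integer label per fiber; the
    run for point ``i`` (position ``idx`` in the list) uses ``ks[idx]``
    centers, k-means++ initialization, and seed ``params.seed + idx``.  A
    cluster count above the fiber count is clamped with a warning.
    """
    if stack is None:
        stack = resample_stack(tractogram, params.npoints)
    n = stack.shape[0]
    batch = params.batch_size or min(max(1, n // 10), 10_000)
    labeling: dict[int, np.ndarray] = {}
    for idx, (pt, k) in enumerate(zip(params.points, params.ks)):
        if k > n:
            warnings.warn(f"k={k} exceeds the fiber count {n}; clamping",
                          RuntimeWarning, stacklevel=2)
            k = n
        km = MiniBatchKMeans(n_clusters=k, init="k-means++", n_init=1,
                             max_iter=params.max_iter, batch_size=batch,
                             random_state=params.seed + idx)
        labeling[pt] = km.fit_predict(stack[:, pt, :])
    return labeling


def stage2_map(labeling: dict[int, np.ndarray]) -> MapClusters:
    """Group fibers by exact equality of their label tuple across selected points."""
    pts = sorted(labeling)
    arr = np.stack([labeling[p] for p in pts], axis=1)  # (n, n_points)
    groups: MapClusters = {}
    for i, row in enumerate(arr):
        groups.setdefault(tuple(int(v) for v in row), []).append(i)
    return groups


def stage3_reassign(clusters: MapClusters, tractogram: Tractogram,
                    params: FFClustParams,
                    stack: np.ndarray | None = None) -> MapClusters:
    """One-pass reassignment of small-cluster fibers to large clusters.

    Every fiber of a cluster of size <= ``small_cluster_max_size`` is compared
    (d_ME, which already minimizes over direct/reversed order) against the
    centroids of all larger clusters, computed once before any move; it joins
    the nearest large cluster when that distance is <= ``assign_thr``, else
    stays.  Large clusters never shrink, and moves never cascade within the
    pass, so the outcome is independent of enumeration order.
    """
    if stack is None:
        stack = resample_stack(tractogram, params.npoints)
    small_max = params.small_cluster_max_size
    large = {t: idx for t, idx in clusters.items() if len(idx) > small_max}
    small = {t: idx for t, idx in clusters.items() if len(idx) <= small_max}
    if not large or not small:
        return {t: sorted(idx) for t, idx in clusters.items()}

    keys = list(large)
    cents = np.asarray([bundle_centroid(stack[large[t]], mode=params.centroid_mode)
                        for t in keys])
    out: MapClusters = {t: list(idx) for t, idx in large.items()}
    for t, idx in small.items():
        keep = []
        for i in idx:
            d = dme_to_many(stack[i], cents)
            j = int(d.argmin())
            if d[j] <= params.assign_thr:
                out[keys[j]].append(i)
            else:
                keep.append(i)
        if keep:
            out[t] = keep
    return {t: sorted(idx) for t, idx in out.items()}


def stage4_merge(clusters: MapClusters, tractogram: Tractogram,
                 params: FFClustParams,
                 stack: np.ndarray | None = None) -> ClusteringResult:
    """Merge clusters sharing the central-point label whose centroids are close.

    Candidate pairs share the Stage-1 label at the central selected point (the
    middle entry of ``params.points``); among candidates, clusters whose
    centroids have d_ME <= ``join_thr`` are merged transitively (union-find).
    Merged centroids are recomputed.  The outcome is independent of cluster
    enumeration order.
    """
    if stack is None:
        stack = resample_stack(tractogram, params.npoints)
    keys = sorted(clusters)  # deterministic enumeration
    cents = np.asarray([bundle_centroid(stack[clusters[t]],
                                        mode=params.centroid_mode)
                        for t in keys])
    central = params.central_point_position

    parent = list(range(len(keys)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_central: dict[int, list[int]] = {}
    for k, t in enumerate(keys):
        by_central.setdefault(t[central], []).append(k)
    for group in by_central.values():
        if len(group) < 2:
            continue
        D = dme_matrix(cents[group])
        for a, b in zip(*np.nonzero(np.triu(D <= params.join_thr, k=1))):
            ri, rj = find(group[a]), find(group[b])
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    merged: dict[int, list[int]] = {}
    for k, t in enumerate(keys):
        merged.setdefault(find(k), []).extend(clusters[t])

    n = len(tractogram)
    labels = np.full(n, -1, dtype=np.int64)
    out_clusters: dict[int, list[int]] = {}
    centroids: dict[int, np.ndarray] = {}
    for cid, root in enumerate(sorted(merged, key=lambda r: min(merged[r]))):
        idx = sorted(merged[root])
        out_clusters[cid] = idx
        labels[idx] = cid
        centroids[cid] = bundle_centroid(stack[idx], mode=params.centroid_mode)
    return ClusteringResult(labels=labels, clusters=out_clusters,
                            centroids=centroids)


def ffclust(tractogram: Tractogram, params: FFClustParams | None = None,
            dir_out: str | os.PathLike | None = None) -> ClusteringResult:
    """Full Stage 1-4 composition; reproducible under ``params.seed``.

    When ``dir_out`` is given, writes final_bundles/, centroids/, bundles_id
    and an outputs/ directory with the per-stage label arrays.
    """
    params = params or FFClustParams()
    stack = resample_stack(tractogram, params.npoints)
    labeling = stage1_point_kmeans(tractogram, params, stack)
    map_clusters = stage2_map(labeling)
    reassigned = stage3_reassign(map_clusters, tractogram, params, stack)
    result = stage4_merge(reassigned, tractogram, params, stack)

    if dir_out is not None:
        dir_out = Path(dir_out)
        export_clustering(result, tractogram, dir_out)
        outputs = dir_out / "outputs"
        outputs.mkdir(parents=True, exist_ok=True)
        np.savetxt(outputs / "stage1_point_labels.txt",
                   np.stack([labeling[p] for p in sorted(labeling)], axis=1),
                   fmt="%d", header="one row per fiber, one column per selected point")
        for name, mapping in (("stage2_map_clusters.txt", map_clusters),
                              ("stage3_clusters.txt", reassigned)):
            with open(outputs / name, "w") as fh:
                for t in sorted(mapping):
                    fh.write(",".join(map(str, t)) + ": "
                             + " ".join(map(str, sorted(mapping[t]))) + "\n")
        np.savetxt(outputs / "stage4_labels.txt", result.labels, fmt="%d")
    return result
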