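"""Average-link agglomerative fiber clustering over an affinity graph, with
adaptive dendrogram partition by maximum intra-cluster distance.

The pairwise d_ME matrix is computed for all fiber pairs; edges of the
affinity graph are kept only where ``d_ij < fiber_thr`` (mm) and carry the
affinity ``a_ij = exp(-d_ij / sigma^2)``.  Average-link agglomeration then
repeatedly merges the pair of clusters with the highest mean pairwise
affinity among connected cluster pairs (clusters with at least one graph edge
between them); clusters in different connected components of the thresholded
graph are never merged, so the result is in general a forest.  Each merge
node records the maximum intra-member pairwise distance, and the tree is
adaptively partitioned top-down: a node becomes a cluster at the shallowest
depth where that maximum drops to ``partition_thr`` (mm) or below.

The merge score maximizes mean *affinity* rather than minimizing mean
distance; the exponential makes the two orderings differ.  The
distance-based variant is available via ``HClustParams.linkage="distance"``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (Tractogram, bundle_centroid, dme_matrix, resample_stack,
                       warn_if_large)
from .results import ClusteringResult, export_clustering

__all__ = ["HClustParams", "Dendrogram", "affinity", "build_dendrogram",
           "adaptive_partition", "hclust"]

MAX_RECOMMENDED_FIBERS = 40_000


@dataclass
class HClustParams:
    """Tunable parameters (all lengths in mm).

    ``fiber_thr``: maximum distance for an affinity-graph edge (default 30).
    ``partition_thr``: adaptive dendrogram partition threshold (default 40).
    ``variance``: similarity scale sigma of the affinity (default 60).
    ``npoints_for_distance``: common resampling point count (default 21).
    ``squared_affinity``: use exp(-d^2/sigma^2) instead of exp(-d/sigma^2).
    ``linkage``: "affinity" (maximize mean affinity, default) or "distance"
    (minimize mean distance).
    """

    fiber_thr: float = 30.0
    partition_thr: float = 40.0
    variance: float = 60.0
    npoints_for_distance: int = 21
    squared_affinity: bool = False
    linkage: str = "affinity"

    def __post_init__(self) -> None:
        for name in ("fiber_thr", "partition_thr", "variance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.npoints_for_distance < 2:
            raise ValueError("npoints_for_distance must be >= 2")
        if self.linkage not in ("affinity", "distance"):
            raise ValueError("linkage must be 'affinity' or 'distance'")


def affinity(d, sigma: float, squared: bool = False):
    """Edge affinity in (0, 1]: ``exp(-d / sigma^2)`` (or ``exp(-d^2/sigma^2)``)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    out = np.exp(-(d * d if squared else d) / (sigma * sigma))
    return float(out) if out.ndim == 0 else out


@dataclass
class Dendrogram:
    """Binary merge forest over fiber leaves.

    Nodes ``0..n-1`` are leaves; internal nodes follow in merge order.
    ``children[k]`` is ``(left, right)`` for internal node ``k`` (None for
    leaves); ``max_intra[k]`` is the maximum pairwise d_ME among the node's
    member fibers (non-decreasing from leaves to root along any path);
    ``score[k]`` is the merge score; ``roots`` lists the forest roots in
    deterministic (min-leaf) order.  ``points`` keeps the resampled fiber
    stack so partitions can compute centroids.
    """

    n_leaves: int
    children: list[tuple[int, int] | None]
    max_intra: list[float]
    score: list[float]
    roots: list[int]
    points: np.ndarray = field(repr=False, default=None)

    def members(self, node: int) -> list[int]:
        """Leaf indices under ``node``, ascending."""
        stack, out = [node], []
        while stack:
            k = stack.pop()
            ch = self.children[k]
            if ch is None:
                out.append(k)
            else:
                stack.extend(ch)
        return sorted(out)


def build_dendrogram(tractogram: Tractogram, params: HClustParams | None = None,
                     precomputed: np.ndarray | None = None) -> Dendrogram:
    """Compute the average-link merge forest over the thresholded affinity graph.

    Merging maximizes the mean pairwise affinity between clusters (over all
    cross pairs), restricted to cluster pairs connected by at least one edge
    (``d < fiber_thr``); ties merge the lexicographically smallest pair of
    minimum leaf indices first.  A single-fiber input yields a single-leaf
    forest.  ``precomputed`` may supply the (n, n) d_ME matrix.
    """
    params = params or HClustParams()
    n = len(tractogram)
    if n == 0:
        raise ValueError("empty tractogram")
    stack = resample_stack(tractogram, params.npoints_for_distance)
    if n == 1:
        return Dendrogram(1, [None], [0.0], [math.nan], [0], stack)

    D = dme_matrix(stack) if precomputed is None else np.asarray(precomputed, float)
    A = affinity(D, params.variance, params.squared_affinity)
    if params.linkage == "distance":
        A = -D  # maximize mean(-d) == minimize mean distance
    edges = (D < params.fiber_thr) & ~np.eye(n, dtype=bool)

    # slot state; merged cluster keeps slot of its smaller-min-leaf child
    S = A.copy()                      # sum of cross-pair link scores
    np.fill_diagonal(S, 0.0)
    M = D.copy()                      # max cross-pair distance
    E = edges.astype(np.int64)        # cross edge count
    size = np.ones(n, dtype=np.int64)
    minleaf = np.arange(n)
    node_of = np.arange(n)            # dendrogram node id held by each slot
    active = np.ones(n, dtype=bool)
    intra = [0.0] * n

    children: list[tuple[int, int] | None] = [None] * n
    max_intra: list[float] = [0.0] * n
    score: list[float] = [math.nan] * n

    while True:
        act = np.flatnonzero(active)
        if len(act) < 2:
            break
        sub_E = E[np.ix_(act, act)]
        if not sub_E.any():
            break
        denom = np.outer(size[act], size[act]).astype(float)
        sc = np.where(sub_E > 0, S[np.ix_(act, act)] / denom, -np.inf)
        np.fill_diagonal(sc, -np.inf)
        best = sc.max()
        ii, jj = np.nonzero(sc == best)
        # deterministic tie-break: smallest sorted (minleaf_i, minleaf_j)
        cand = [(tuple(sorted((minleaf[act[a]], minleaf[act[b]]))), act[a], act[b])
                for a, b in zip(ii, jj) if a < b]
        cand.sort()
        _, i, j = cand[0]
        if minleaf[j] < minleaf[i]:
            i, j = j, i

        new_id = len(children)
        node_intra = max(intra[i], intra[j], float(M[i, j]))
        children.append((node_of[i], node_of[j]))
        max_intra.append(node_intra)
        score.append(float(best))

        S[i, :] += S[j, :]
        S[:, i] = S[i, :]
        np.maximum(M[i, :], M[j, :], out=M[i, :])
        M[:, i] = M[i, :]
        E[i, :] += E[j, :]
        E[:, i] = E[i, :]
        size[i] += size[j]
        intra[i] = node_intra
        node_of[i] = new_id
        active[j] = False
        S[i, i] = 0.0
        E[i, i] = 0
        M[i, i] = 0.0

    dendro = Dendrogram(n, children, max_intra, score, [], stack)
    dendro.roots = sorted((int(node_of[s]) for s in np.flatnonzero(active)),
                          key=lambda nd: min(dendro.members(nd)))
    return dendro


def adaptive_partition(dendro: Dendrogram, partition_thr: float,
                       centroid_mode: str = "mean") -> ClusteringResult:
    """Cut the merge forest top-down at the shallowest nodes whose maximum
    intra-member pairwise distance is <= ``partition_thr`` (mm); leaves always
    terminate, so every fiber lands in exactly one cluster."""
    accepted: list[int] = []
    for root in dendro.roots:
        stack = [root]
        while stack:
            node = stack.pop()
            if dendro.max_intra[node] <= partition_thr or dendro.children[node] is None:
                accepted.append(node)
            else:
                left, right = dendro.children[node]
                stack.extend((right, left))
    accepted.sort(key=lambda nd: min(dendro.members(nd)))

    labels = np.full(dendro.n_leaves, -1, dtype=np.int64)
    clusters: dict[int, list[int]] = {}
    centroids: dict[int, np.ndarray] = {}
    for cid, node in enumerate(accepted):
        mem = dendro.members(node)
        labels[mem] = cid
        clusters[cid] = mem
        if dendro.points is not None:
            centroids[cid] = bundle_centroid(dendro.points[mem], mode=centroid_mode)
    return ClusteringResult(labels=labels, clusters=clusters, centroids=centroids)


def hclust(tractogram: Tractogram, params: HClustParams | None = None,
           dir_out: str | os.PathLike | None = None) -> ClusteringResult:
    """Full pipeline: dendrogram construction + adaptive partition (+ export).

    When ``dir_out`` is given, writes final_bundles/, centroids/, bundles_id
    and an outputs/ directory with intermediate results (condensed distance
    matrix, affinity-graph edge list, dendrogram serialization).
    """
    params = params or HClustParams()
    warn_if_large(len(tractogram), MAX_RECOMMENDED_FIBERS, "hclust")
    stack = resample_stack(tractogram, params.npoints_for_distance)
    D = dme_matrix(stack)
    dendro = build_dendrogram(tractogram, params, precomputed=D)
    result = adaptive_partition(dendro, params.partition_thr)

    if dir_out is not None:
        dir_out = Path(dir_out)
        export_clustering(result, tractogram, dir_out)
        outputs = dir_out / "outputs"
        outputs.mkdir(parents=True, exist_ok=True)
        n = len(tractogram)
        iu = np.triu_indices(n, k=1)
        np.savetxt(outputs / "distance_matrix_condensed.txt", D[iu], fmt="%.6f")
        with open(outputs / "edges.txt", "w") as fh:
            for a, b in zip(*iu):
                if D[a, b] < params.fiber_thr:
                    fh.write(f"{a} {b} {D[a, b]:.6f}\n")
        with open(outputs / "dendrogram.txt", "w") as fh:
            fh.write(f"n_leaves {dendro.n_leaves}\n")
            fh.write("roots " + " ".join(map(str, dendro.roots)) + "\n")
            for k, ch in enumerate(dendro.children):
                if ch is not None:
                    fh.write(f"node {k} children {ch[0]} {ch[1]} "
                             f"max_intra {dendro.max_intra[k]:.6f} "
                             f"score {dendro.score[k]:.9f}\n")
    return result
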