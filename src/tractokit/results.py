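"""Shared clustering result container and exporters (used by both clustering
algorithms)."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import Tractogram
from .io_formats import write_bundles, write_bundles_id

__all__ = ["ClusteringResult", "export_clustering"]


@dataclass
class ClusteringResult:
    """Cluster assignment over a tractogram.

    ``labels[i]`` is the cluster id of fiber ``i``; ``clusters`` maps cluster
    id to the ascending original fiber indices; ``centroids`` maps cluster id
    to a representative fiber (common resampled point count).
    """

    labels: np.ndarray
    clusters: dict[int, list[int]]
    centroids: dict[int, np.ndarray] = field(default_factory=dict)

    def n_clusters(self) -> int:
        return len(self.clusters)


def export_clustering(result: ClusteringResult, tractogram: Tractogram,
                      dir_out: str | os.PathLike, prefix: str = "cluster") -> None:
    """Write final_bundles/ (one *bundles* file per cluster), centroids/
    (single labeled file), and the bundles_id table."""
    dir_out = Path(dir_out)
    fb = dir_out / "final_bundles"
    cd = dir_out / "centroids"
    fb.mkdir(parents=True, exist_ok=True)
    cd.mkdir(parents=True, exist_ok=True)
    for cid, idx in result.clusters.items():
        name = f"{prefix}_{cid:05d}"
        write_bundles(Tractogram(fibers=[tractogram[i] for i in idx],
                                 labels=[(name, 0)]),
                      fb / f"{name}.bundles")
    if result.centroids:
        ids = sorted(result.centroids)
        cent = Tractogram(
            fibers=[result.centroids[c].astype(np.float32) for c in ids],
            labels=[(f"{prefix}_{c:05d}", k) for k, c in enumerate(ids)])
        write_bundles(cent, cd / "centroids.bundles")
    write_bundles_id({f"{prefix}_{c:05d}": idx
                      for c, idx in sorted(result.clusters.items())},
                     dir_out / "bundles_id.txt")
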