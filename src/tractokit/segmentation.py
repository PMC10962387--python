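"""Atlas-based white-matter bundle segmentation (nearest-centroid d_ME).

Each subject fiber is resampled to the atlas point count (21), compared against
every atlas centroid with the d_ME distance, and assigned to the bundle owning
the globally closest centroid — provided that distance does not exceed that
bundle's threshold (mm); otherwise the fiber is left unassigned.  On equal
distance the bundle appearing first in the atlas table wins.  Output fibers
keep their original (un-resampled) geometry.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (Tractogram, bundle_centroid, dme_matrix, resample_stack)
from .io_formats import (ATLAS_NPOINTS, BundleAtlas, write_bundles,
                         write_bundles_id)

__all__ = ["SegmentationResult", "fiberseg", "export_segmentation"]


@dataclass
class SegmentationResult:
    """Per-bundle fiber assignment against an atlas.

    ``assignments`` maps bundle name to the ascending original fiber indices
    assigned to it (every bundle of the atlas appears, possibly empty);
    ``centroids`` holds the pointwise-mean centroid of each non-empty bundle's
    assigned fibers (21 points); ``unassigned`` lists the leftover indices.
    """

    assignments: dict[str, list[int]]
    centroids: dict[str, np.ndarray]
    unassigned: list[int]
    distances: np.ndarray | None = field(default=None, repr=False)


def fiberseg(tractogram: Tractogram, atlas: BundleAtlas,
             thresholds: dict[str, float] | None = None) -> SegmentationResult:
    """Classify subject fibers against a bundle atlas.

    Parameters
    ----------
    tractogram
        Subject fibers (any per-fiber point count; resampled internally to the
        atlas point count for the comparison only).
    atlas
        Bundle atlas; per-bundle thresholds come from its table.
    thresholds
        Optional per-bundle threshold overrides (mm), keyed by bundle name.
    """
    if len(tractogram) == 0:
        raise ValueError("empty tractogram")
    if len(atlas) == 0:
        raise ValueError("empty atlas")
    thresholds = thresholds or {}

    cent_stack = []
    cent_bundle = []  # bundle index per centroid, in atlas order
    thr = np.empty(len(atlas))
    names = []
    for b, entry in enumerate(atlas):
        names.append(entry.name)
        thr[b] = float(thresholds.get(entry.name, entry.threshold_mm))
        for c in entry.centroids:
            cent_stack.append(c)
            cent_bundle.append(b)
    cent_stack = np.asarray(cent_stack, dtype=np.float64)
    cent_bundle = np.asarray(cent_bundle)

    sub = resample_stack(tractogram, ATLAS_NPOINTS)
    D = dme_matrix(sub, cent_stack)  # (n_fibers, n_centroids)
    best = D.argmin(axis=1)  # first-centroid tie-break = atlas order
    dmin = D[np.arange(len(sub)), best]
    owner = cent_bundle[best]
    ok = dmin <= thr[owner]

    assignments: dict[str, list[int]] = {n: [] for n in names}
    for i in np.flatnonzero(ok):
        assignments[names[owner[i]]].append(int(i))
    unassigned = [int(i) for i in np.flatnonzero(~ok)]

    centroids = {}
    for name, idx in assignments.items():
        if idx:
            centroids[name] = bundle_centroid(sub[idx])
    return SegmentationResult(assignments=assignments, centroids=centroids,
                              unassigned=unassigned, distances=dmin)


def export_segmentation(result: SegmentationResult, tractogram: Tractogram,
                        dir_out: str | os.PathLike, subj_name: str) -> None:
    """Write final_bundles/ (one *bundles* file per non-empty bundle),
    centroids/ (single file, one labeled centroid per segmented bundle), and
    the bundles_id index table."""
    dir_out = Path(dir_out)
    fb = dir_out / "final_bundles"
    cd = dir_out / "centroids"
    fb.mkdir(parents=True, exist_ok=True)
    cd.mkdir(parents=True, exist_ok=True)

    for name, idx in result.assignments.items():
        if not idx:
            continue
        sub = Tractogram(fibers=[tractogram[i] for i in idx], labels=[(name, 0)])
        write_bundles(sub, fb / f"{subj_name}_{name}.bundles")

    non_empty = [n for n, idx in result.assignments.items() if idx]
    if non_empty:
        cent_t = Tractogram(
            fibers=[result.centroids[n].astype(np.float32) for n in non_empty],
            labels=[(n, k) for k, n in enumerate(non_empty)])
        write_bundles(cent_t, cd / f"{subj_name}_centroids.bundles")

    write_bundles_id(result.assignments, dir_out / "bundles_id.txt")
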