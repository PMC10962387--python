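"""Tractogram utilities: deformation-field application, inter-set intersection
percentages, and per-bundle metrics with range filtering."""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .geometry import (Tractogram, dme_matrix, fiber_length, resample_stack)
from .io_formats import BundlesFormatError, DeformationField, read_bundles

__all__ = ["deform", "intersection", "postprocessing_metrics", "filter_bundles"]

log = logging.getLogger("tractokit")


def deform(field: DeformationField, tractogram: Tractogram,
           mode: str = "displacement") -> Tractogram:
    """Apply a voxel-gridded deformation to every fiber point.

    Each world-mm point is mapped to voxel coordinates through the inverse of
    the field's affine, the per-voxel vector is trilinearly interpolated, and
    the result is ``point + vector`` (``mode="displacement"``, the default) or
    the vector itself taken as the absolute target position
    (``mode="absolute"``, for warp files storing dense coordinate maps).
    Points outside the grid use the nearest-edge voxel's value (clamped); the
    clamp count is logged.  Topology and per-fiber point counts are unchanged.
    """
    if mode not in ("displacement", "absolute"):
        raise ValueError("mode must be 'displacement' or 'absolute'")
    inv = np.linalg.inv(field.affine)
    counts = [f.shape[0] for f in tractogram]
    pts = np.concatenate([np.asarray(f, dtype=np.float64) for f in tractogram])
    vox = pts @ inv[:3, :3].T + inv[:3, 3]

    upper = np.asarray(field.grid.shape[:3], dtype=np.float64) - 1.0
    clamped = int(np.any((vox < 0) | (vox > upper), axis=1).sum())
    if clamped:
        log.warning("deform: %d of %d points outside the field grid were clamped "
                    "to the nearest edge voxel", clamped, len(vox))

    coords = vox.T  # (3, N)
    disp = np.stack([map_coordinates(field.grid[..., c], coords, order=1,
                                     mode="nearest") for c in range(3)], axis=1)
    out_pts = disp if mode == "absolute" else pts + disp

    fibers, off = [], 0
    for f, n in zip(tractogram, counts):
        fibers.append(out_pts[off:off + n].astype(np.asarray(f).dtype, copy=False))
        off += n
    return Tractogram(fibers=fibers, labels=tractogram.labels,
                      space_tag=tractogram.space_tag)


def intersection(a: Tractogram, b: Tractogram, distance_thr: float,
                 npoints: int = 21) -> tuple[float, float]:
    """Percentage of fibers of each set having a similar fiber in the other.

    Fibers are resampled to a common point count; fiber ``x`` of ``a`` is
    matched when ``min_y d_ME(x, y) <= distance_thr`` over ``y`` in ``b``.
    Returns ``(100 * matched_a / |a|, 100 * matched_b / |b|)``, both in
    [0, 100].
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("intersection requires two non-empty fiber sets")
    if distance_thr <= 0:
        raise ValueError("distance_thr must be > 0")
    D = dme_matrix(resample_stack(a, npoints), resample_stack(b, npoints))
    pct_a = 100.0 * float((D.min(axis=1) <= distance_thr).mean())
    pct_b = 100.0 * float((D.min(axis=0) <= distance_thr).mean())
    return pct_a, pct_b


def postprocessing_metrics(bundle_dir: str | os.PathLike,
                           npoints: int = 21) -> pd.DataFrame:
    """Per-bundle metrics table over a directory of *bundles* files.

    One row per readable file (row key = file name stem): ``size`` (fiber
    count), ``mean_length_mm`` (mean polyline length over the original
    geometry), and ``intra_distance_mm`` (maximum pairwise d_ME over fibers
    resampled to ``npoints``; 0 for a single-fiber bundle).  Unreadable files
    are skipped with a logged warning.
    """
    bundle_dir = Path(bundle_dir)
    paths = sorted(bundle_dir.glob("*.bundles"))
    if not paths:
        raise ValueError(f"no *.bundles files in {bundle_dir}")
    rows = {}
    for path in paths:
        try:
            t = read_bundles(path)
        except BundlesFormatError as exc:
            log.warning("postprocessing: skipping unreadable %s (%s)", path, exc)
            continue
        stack = resample_stack(t, npoints)
        intra = float(dme_matrix(stack).max()) if len(t) > 1 else 0.0
        rows[path.stem] = {
            "size": len(t),
            "mean_length_mm": float(np.mean([fiber_length(f) for f in t])),
            "intra_distance_mm": intra,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "name"
    return df


def _range_mask(values: pd.Series, rng: tuple | None) -> pd.Series:
    if rng is None:
        return pd.Series(True, index=values.index)
    lo, hi = rng
    if lo is not None and hi is not None and lo > hi:
        raise ValueError(f"inverted range: {rng}")
    mask = pd.Series(True, index=values.index)
    if lo is not None:
        mask &= values >= lo
    if hi is not None:
        mask &= values <= hi
    return mask


def filter_bundles(table: pd.DataFrame,
                   size_range: tuple | None = None,
                   length_range: tuple | None = None,
                   intra_range: tuple | None = None) -> pd.DataFrame:
    """Subset a metrics table by closed numeric ranges (ALL given ranges must
    hold; a ``None`` bound is open, a ``None`` range passes everything)."""
    mask = (_range_mask(table["size"], size_range)
            & _range_mask(table["mean_length_mm"], length_range)
            & _range_mask(table["intra_distance_mm"], intra_range))
    return table[mask]
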