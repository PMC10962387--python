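"""Fiber and tractogram data model, resampling, and the maximum-corresponding-point
Euclidean fiber distance (d_ME).

A *fiber* (streamline) is an ordered 3D polyline in millimeters, stored as an
``(n_points, 3)`` float array.  A *tractogram* is an ordered collection of fibers,
optionally carrying a contiguous bundle labeling (name, start-index pairs).

The central similarity measure is the maximum Euclidean distance between
corresponding points of two equal-length fibers, minimized over the direct and
the reversed point order of the second fiber::

    d_ME(A, B) = min( max_i |a_i - b_i| , max_i |a_i - b_rev_i| )

All algorithms in this package (atlas segmentation, both clustering methods,
intersection) are built on d_ME, so fibers must be resampled to a common point
count before comparison; :func:`resample` provides arc-length-uniform resampling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "EXCEEDS",
    "Fiber",
    "Tractogram",
    "fiber_length",
    "resample",
    "resample_stack",
    "dme",
    "dme_with_cutoff",
    "dme_matrix",
    "dme_to_many",
    "bundle_centroid",
]

#: Sentinel returned by :func:`dme_with_cutoff` when both the direct and the
#: reversed branch exceed the cutoff.  Infinity compares correctly with any
#: finite distance, so ``result <= cutoff`` distinguishes the two outcomes.
EXCEEDS: float = math.inf

#: Alias used in signatures: a fiber is an (n, 3) float array, n >= 2.
Fiber = np.ndarray


def as_fiber(points, dtype=np.float64) -> np.ndarray:
    """Coerce ``points`` to a validated (n, 3) float array with n >= 2."""
    arr = np.asarray(points, dtype=dtype)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"a fiber must be an (n, 3) array, got shape {arr.shape}")
    if arr.shape[0] < 2:
        raise ValueError("a fiber needs at least 2 points")
    if not np.all(np.isfinite(arr)):
        raise ValueError("fiber coordinates must be finite")
    return arr


@dataclass
class Tractogram:
    """Ordered fiber collection with optional contiguous bundle labeling.

    Parameters
    ----------
    fibers
        List of (n_i, 3) arrays, n_i >= 2, coordinates in world millimeters.
    labels
        Optional ``[(name, start_index), ...]`` with strictly increasing start
        indices beginning at 0; range ``i`` covers fibers
        ``[start_i, start_{i+1})`` (last range extends to ``len(fibers)``).
    space_tag
        Free-text coordinate-frame note (e.g. ``"MNI"``).
    """

    fibers: list[np.ndarray]
    labels: list[tuple[str, int]] | None = None
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.fibers = [as_fiber(f, dtype=np.asarray(f).dtype
                                if np.asarray(f).dtype in (np.float32, np.float64)
                                else np.float64)
                       for f in self.fibers]
        if self.labels is not None:
            self.labels = [(str(n), int(s)) for n, s in self.labels]
            self._check_labels()

    def _check_labels(self) -> None:
        starts = [s for _, s in self.labels]
        if starts and starts[0] != 0:
            raise ValueError("first label start_index must be 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("label start_index values must be strictly increasing")
        if starts and starts[-1] >= max(len(self.fibers), 1):
            raise ValueError("label start_index beyond fiber count")

    def __len__(self) -> int:
        return len(self.fibers)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.fibers)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.fibers[i]

    def label_ranges(self) -> list[tuple[str, int, int]]:
        """Return ``(name, start, stop)`` per bundle; one default range if unlabeled."""
        if not self.labels:
            return [("all", 0, len(self.fibers))]
        out = []
        for k, (name, start) in enumerate(self.labels):
            stop = self.labels[k + 1][1] if k + 1 < len(self.labels) else len(self.fibers)
            out.append((name, start, stop))
        return out

    def fiber_labels(self) -> np.ndarray:
        """Per-fiber integer label derived from the contiguous ranges."""
        lab = np.zeros(len(self.fibers), dtype=np.int64)
        for k, (_, start, stop) in enumerate(self.label_ranges()):
            lab[start:stop] = k
        return lab


def fiber_length(fiber: Fiber) -> float:
    """Polyline length in mm: sum of Euclidean lengths of consecutive segments."""
    f = np.asarray(fiber, dtype=np.float64)
    return float(np.linalg.norm(np.diff(f, axis=0), axis=1).sum())


def resample(fiber: Fiber, npoints: int) -> Fiber:
    """Resample a fiber to ``npoints`` equidistant points along its arc length.

    Endpoints are preserved exactly; interior points are linearly interpolated
    within the original segments at arc-length positions
    ``k * L / (npoints - 1)``.  Zero-length segments (repeated points)
    contribute zero arc length and are tolerated.
    """
    if npoints < 2:
        raise ValueError("npoints must be >= 2")
    f = np.asarray(fiber, dtype=np.float64)
    seg = np.linalg.norm(np.diff(f, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0.0:  # degenerate: all points coincide
        return np.repeat(f[:1], npoints, axis=0).astype(fiber.dtype, copy=False)
    t = np.linspace(0.0, total, npoints)
    out = np.column_stack([np.interp(t, s, f[:, k]) for k in range(3)])
    out[0], out[-1] = f[0], f[-1]
    return out.astype(np.asarray(fiber).dtype, copy=False)


def resample_stack(fibers: Sequence[Fiber] | Tractogram, npoints: int) -> np.ndarray:
    """Resample every fiber and stack into an ``(n_fibers, npoints, 3)`` float64 array."""
    return np.asarray([resample(np.asarray(f, dtype=np.float64), npoints)
                       for f in fibers], dtype=np.float64)


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(
            f"d_ME requires equal point counts, got {a.shape[0]} and {b.shape[0]}; "
            "resample first")
    return a, b


def dme(a: Fiber, b: Fiber) -> float:
    """Maximum corresponding-point Euclidean distance, min over direct/reversed order."""
    a, b = _check_pair(a, b)
    direct = np.linalg.norm(a - b, axis=1).max()
    reverse = np.linalg.norm(a - b[::-1], axis=1).max()
    return float(min(direct, reverse))


def dme_with_cutoff(a: Fiber, b: Fiber, cutoff: float) -> float:
    """d_ME with early abandon: returns :data:`EXCEEDS` when d_ME(a, b) > cutoff.

    Each branch (direct and reversed correspondence) stops as soon as its
    running maximum exceeds ``cutoff``; the numeric value is returned only when
    at least one branch stays within the cutoff, and then equals ``dme(a, b)``
    exactly (a branch abandoned above the cutoff cannot be the minimum).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    a, b = _check_pair(a, b)
    c2 = cutoff * cutoff

    def branch(bb: np.ndarray) -> float:
        run = 0.0
        for i in range(a.shape[0]):
            d = a[i] - bb[i]
            q = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
            if q > run:
                run = q
                if run > c2:
                    return math.inf
        return math.sqrt(run)

    direct = branch(b)
    reverse = branch(b[::-1])
    best = min(direct, reverse)
    return EXCEEDS if best > cutoff else best


def dme_matrix(A: np.ndarray, B: np.ndarray | None = None,
               chunk: int = 256) -> np.ndarray:
    """Pairwise d_ME between stacked resampled fibers.

    ``A`` is (n, p, 3); ``B`` is (m, p, 3) or None for the symmetric case.
    Returns an (n, m) float64 matrix.  Computed in row chunks to bound memory.
    """
    A = np.asarray(A, dtype=np.float64)
    B = A if B is None else np.asarray(B, dtype=np.float64)
    n, m = A.shape[0], B.shape[0]
    out = np.empty((n, m), dtype=np.float64)
    Brev = B[:, ::-1, :]
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        blk = A[lo:hi, None, :, :]  # (c,1,p,3)
        d1 = np.linalg.norm(blk - B[None], axis=3).max(axis=2)
        d2 = np.linalg.norm(blk - Brev[None], axis=3).max(axis=2)
        out[lo:hi] = np.minimum(d1, d2)
    return out


def dme_to_many(f: Fiber, stack: np.ndarray) -> np.ndarray:
    """d_ME from one fiber to every fiber of an (m, p, 3) stack; returns (m,)."""
    f = np.asarray(f, dtype=np.float64)
    d1 = np.linalg.norm(stack - f, axis=2).max(axis=1)
    d2 = np.linalg.norm(stack - f[::-1], axis=2).max(axis=1)
    return np.minimum(d1, d2)


def bundle_centroid(fibers: Sequence[Fiber], mode: str = "mean") -> Fiber:
    """Representative trajectory of a fiber set (all fibers same point count).

    ``mode="mean"`` (default): orientation-align every fiber to the first one —
    a fiber is flipped when the reversed point order gives a smaller maximum
    corresponding-point distance to the reference — then return the pointwise
    mean polyline.  ``mode="medoid"``: return the member fiber minimizing the
    summed d_ME to all other members.
    """
    if len(fibers) == 0:
        raise ValueError("bundle_centroid needs a non-empty fiber list")
    stack = np.asarray([np.asarray(f, dtype=np.float64) for f in fibers])
    if stack.ndim != 3:
        raise ValueError("all fibers must share the same point count; resample first")
    if mode == "medoid":
        D = dme_matrix(stack)
        return stack[int(D.sum(axis=1).argmin())]
    if mode != "mean":
        raise ValueError(f"unknown centroid mode {mode!r}")
    ref = stack[0]
    d_dir = np.linalg.norm(stack - ref, axis=2).max(axis=1)
    d_rev = np.linalg.norm(stack[:, ::-1, :] - ref, axis=2).max(axis=1)
    aligned = np.where((d_rev < d_dir)[:, None, None], stack[:, ::-1, :], stack)
    return aligned.mean(axis=0)


def warn_if_large(n: int, limit: int, algo: str) -> None:
    if n > limit:
        warnings.warn(
            f"{algo} received {n} fibers; recommended maximum is {limit} "
            "(pairwise-distance cost grows quadratically)",
            RuntimeWarning, stacklevel=3)
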