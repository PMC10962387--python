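"""Synthetic tractography phantoms: labeled multi-bundle fiber sets, matching
atlases, and analytic deformation fields.

Each phantom bundle is a set of noisy copies of a parametric backbone curve
(line, circular arc, U-shape, or helix): the backbone is sampled at a per-fiber
random point count, i.i.d. Gaussian offsets with a perpendicular bias are added
(tangential components are attenuated, mimicking tract-like dispersion around a
trajectory), and about half of the fibers are stored in reversed point order to
exercise the orientation handling of the d_ME distance.  Everything is fully
deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Fiber, Tractogram, dme, resample
from .io_formats import (AtlasBundleEntry, BundleAtlas, DeformationField,
                         ATLAS_NPOINTS)

__all__ = [
    "BundleSpec",
    "PhantomSpec",
    "make_backbone",
    "make_bundle",
    "make_phantom",
    "phantom_atlas",
    "make_deformation_field",
]

_DENSE = 200  # dense backbone sampling before per-fiber resampling


def make_backbone(kind: str, params: dict | None = None,
                  npoints: int = _DENSE) -> Fiber:
    """Sample a parametric backbone curve as an (npoints, 3) polyline.

    Kinds and their parameters (all lengths in mm):

    - ``line``: ``start`` (3,), ``direction`` (3,), ``length`` (default 80)
    - ``arc``: circle arc; ``center`` (3,), ``radius`` (40), ``angle_deg``
      span (120), ``plane`` two orthonormal 3-vectors (xy plane default)
    - ``u_shape``: 180-degree arc with short straight legs; ``center``,
      ``radius`` (25), ``leg`` (15)
    - ``helix``: ``center``, ``radius`` (15), ``pitch`` rise per turn (30),
      ``turns`` (1.5)
    """
    p = dict(params or {})
    t = np.linspace(0.0, 1.0, npoints)
    if kind == "line":
        start = np.asarray(p.get("start", (0.0, 0.0, 0.0)), dtype=float)
        d = np.asarray(p.get("direction", (1.0, 0.0, 0.0)), dtype=float)
        d = d / np.linalg.norm(d)
        return start + np.outer(t * float(p.get("length", 80.0)), d)
    if kind in ("arc", "u_shape"):
        center = np.asarray(p.get("center", (0.0, 0.0, 0.0)), dtype=float)
        radius = float(p.get("radius", 40.0 if kind == "arc" else 25.0))
        u = np.asarray(p.get("plane", ((1, 0, 0), (0, 1, 0)))[0], dtype=float)
        v = np.asarray(p.get("plane", ((1, 0, 0), (0, 1, 0)))[1], dtype=float)
        if kind == "arc":
            span = np.deg2rad(float(p.get("angle_deg", 120.0)))
            ang = t * span
            return center + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
        leg = float(p.get("leg", 15.0))
        ang = np.linspace(0.0, np.pi, npoints)
        curve = center + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
        nleg = max(2, npoints // 8)
        down = -v / np.linalg.norm(v)
        first = curve[0] + np.outer(np.linspace(leg, 0.0, nleg, endpoint=False), down)
        last = curve[-1] + np.outer(np.linspace(0.0, leg, nleg + 1)[1:], down)
        return resample(np.vstack([first, curve, last]), npoints)
    if kind == "helix":
        center = np.asarray(p.get("center", (0.0, 0.0, 0.0)), dtype=float)
        radius = float(p.get("radius", 15.0))
        pitch = float(p.get("pitch", 30.0))
        turns = float(p.get("turns", 1.5))
        ang = t * 2.0 * np.pi * turns
        return center + np.column_stack([radius * np.cos(ang),
                                         radius * np.sin(ang),
                                         t * pitch * turns])
    raise ValueError(f"unknown backbone kind {kind!r}")


@dataclass
class BundleSpec:
    """One phantom bundle: a backbone family plus noise/sampling parameters."""

    kind: str = "line"
    params: dict = field(default_factory=dict)
    n_fibers: int = 100
    jitter_sd: float = 1.0  # mm, per-point Gaussian dispersion
    npoints_range: tuple[int, int] = (21, 21)  # inclusive

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass
class PhantomSpec:
    """A multi-bundle phantom: bundle specs plus the master seed."""

    bundles: list[BundleSpec]
    seed: int = 0


def _perpendicular_bias(offsets: np.ndarray, points: np.ndarray,
                        tangential_scale: float = 0.3) -> np.ndarray:
    """Attenuate the tangential component of per-point offsets.

    Tangents are central differences of the backbone polyline; the component of
    each offset along the local tangent is scaled by ``tangential_scale`` so
    dispersion is mostly perpendicular to the trajectory (fibers of a tract run
    alongside each other rather than sliding along each other).
    """
    tang = np.gradient(points, axis=0)
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tang = tang / norms
    along = (offsets * tang).sum(axis=1, keepdims=True)
    return offsets + (tangential_scale - 1.0) * along * tang


def make_bundle(backbone: Fiber, n_fibers: int, jitter_sd: float,
                npoints_range: tuple[int, int] = (21, 21),
                seed: int | np.random.Generator = 0) -> list[Fiber]:
    """Generate ``n_fibers`` noisy copies of a backbone polyline.

    Each fiber resamples the backbone at a uniform-random point count within
    ``npoints_range`` (inclusive), adds i.i.d. perpendicular-biased Gaussian
    offsets of standard deviation ``jitter_sd`` mm, and is stored in reversed
    point order with probability one half.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = npoints_range
    if lo < 2 or hi < lo:
        raise ValueError(f"invalid npoints_range {npoints_range}")
    fibers: list[Fiber] = []
    for _ in range(n_fibers):
        npts = int(rng.integers(lo, hi + 1))
        f = resample(np.asarray(backbone, dtype=np.float64), npts)
        if jitter_sd > 0:
            off = rng.normal(scale=jitter_sd, size=f.shape)
            f = f + _perpendicular_bias(off, f)
        if rng.random() < 0.5:
            f = f[::-1].copy()
        fibers.append(f)
    return fibers


def make_phantom(spec: PhantomSpec, shuffle: bool = False
                 ) -> tuple[Tractogram, np.ndarray, dict]:
    """Build a labeled multi-bundle phantom.

    Returns ``(tractogram, labels, info)``: per-fiber integer ground-truth
    labels (bundle order of ``spec.bundles``) and an info dict with the
    resampled 21-point backbones (``"backbones"``) and the pairwise backbone
    d_ME separation matrix (``"separation_mm"``), enabling separation-aware
    tests.  With ``shuffle=True`` the fibers are permuted (label array is
    permuted in step; the tractogram then carries no contiguous label ranges).
    """
    rng = np.random.default_rng(spec.seed)
    fibers: list[Fiber] = []
    labels: list[int] = []
    ranges: list[tuple[str, int]] = []
    backbones = []
    for k, b in enumerate(spec.bundles):
        bb = make_backbone(b.kind, b.params)
        backbones.append(resample(bb, 21))
        ranges.append((f"bundle_{k:02d}", len(fibers)))
        fibers += make_bundle(bb, b.n_fibers, b.jitter_sd, b.npoints_range, rng)
        labels += [k] * b.n_fibers
    lab = np.asarray(labels, dtype=np.int64)
    nb = len(backbones)
    sep = np.zeros((nb, nb))
    for i in range(nb):
        for j in range(i + 1, nb):
            sep[i, j] = sep[j, i] = dme(backbones[i], backbones[j])
    info = {"backbones": backbones, "separation_mm": sep}
    if shuffle:
        perm = rng.permutation(len(fibers))
        fibers = [fibers[i] for i in perm]
        lab = lab[perm]
        return Tractogram(fibers=fibers), lab, info
    return Tractogram(fibers=fibers, labels=ranges), lab, info


def phantom_atlas(spec: PhantomSpec, threshold_factor: float = 3.0,
                  min_threshold: float = 0.5) -> BundleAtlas:
    """Derive a bundle atlas from a phantom spec: 21-point backbones as
    centroids, per-bundle threshold ``max(threshold_factor * jitter_sd,
    min_threshold)`` mm."""
    entries = []
    for k, b in enumerate(spec.bundles):
        bb = resample(make_backbone(b.kind, b.params), ATLAS_NPOINTS)
        thr = max(threshold_factor * b.jitter_sd, min_threshold)
        entries.append(AtlasBundleEntry(name=f"bundle_{k:02d}", threshold_mm=thr,
                                        size=b.n_fibers, centroids=[bb]))
    return BundleAtlas(entries=entries)


def make_deformation_field(kind: str, grid_shape: tuple[int, int, int] = (10, 10, 10),
                           affine: np.ndarray | None = None,
                           params: dict | None = None,
                           seed: int = 0) -> DeformationField:
    """Build an analytic displacement field on a voxel grid.

    Kinds: ``zero``; ``constant`` (params: ``vector``); ``affine`` (params:
    ``A`` 3x3, ``t`` 3-vector — displacement at voxel v is (A x(v) + t) - x(v)
    with x(v) the world coordinate); ``smooth_random`` (params: ``amplitude``
    mm, low-frequency sinusoidal mixture seeded by ``seed``).
    """
    if any(s < 2 for s in grid_shape):
        raise ValueError("grid_shape needs >= 2 voxels per axis")
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    p = dict(params or {})
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in grid_shape],
                               indexing="ij"), axis=-1).astype(float)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    if kind == "zero":
        grid = np.zeros(grid_shape + (3,))
    elif kind == "constant":
        vec = np.asarray(p.get("vector", (1.0, 2.0, 3.0)), dtype=float)
        grid = np.broadcast_to(vec, grid_shape + (3,)).copy()
    elif kind == "affine":
        A = np.asarray(p.get("A", np.eye(3)), dtype=float)
        t = np.asarray(p.get("t", np.zeros(3)), dtype=float)
        grid = world @ A.T + t - world
    elif kind == "smooth_random":
        rng = np.random.default_rng(seed)
        amp = float(p.get("amplitude", 2.0))
        extent = np.maximum(world.max(axis=(0, 1, 2)) - world.min(axis=(0, 1, 2)), 1e-9)
        grid = np.zeros(grid_shape + (3,))
        for c in range(3):
            for _ in range(3):
                freq = rng.uniform(0.5, 1.5, size=3) * np.pi / extent
                phase = rng.uniform(0, 2 * np.pi)
                w = rng.normal()
                grid[..., c] += w * np.sin((world * freq).sum(axis=-1) + phase)
        grid *= amp / max(np.abs(grid).max(), 1e-12)
    else:
        raise ValueError(f"unknown deformation kind {kind!r}")
    return DeformationField(grid=grid, affine=affine)
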