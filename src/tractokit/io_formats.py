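"""Readers and writers for tractography and atlas data.

Native format is the BrainVISA-style *bundles* pair: a text metadata file
``name.bundles`` holding a key/value attribute block (curves count, byte order,
bundle labels as alternating name/start-index entries) and a binary companion
``name.bundlesdata`` holding, per fiber, a little-endian uint32 point count
followed by ``n_points`` interleaved x,y,z IEEE-754 32-bit floats.  The format
supports several labeled bundles in one file via contiguous index ranges.

TRK (TrackVis) and TCK (MRtrix) conversion goes through nibabel; all fibers are
held in memory in world millimeters (TRK voxel-ordered points are mapped
through the header affine with the standard half-voxel origin convention, as
nibabel does; TCK points are world mm already).

Deformation fields are NIfTI images whose last dimension holds a 3-vector of
per-voxel displacements; atlases are a directory of per-bundle fiber files
plus a text table of name / distance threshold (mm) / size.
"""

from __future__ import annotations

import ast
import os
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import Fiber, Tractogram

__all__ = [
    "BundlesFormatError",
    "TractogramIntegrityError",
    "AtlasFormatError",
    "MissingBundleError",
    "AtlasBundleEntry",
    "BundleAtlas",
    "DeformationField",
    "read_bundles",
    "write_bundles",
    "convert_tractogram",
    "read_deformation_field",
    "read_atlas",
    "write_atlas",
    "write_bundles_id",
    "read_bundles_id",
]

ATLAS_NPOINTS = 21  # atlas centroids are sampled at 21 equidistant points


class BundlesFormatError(ValueError):
    """Malformed or missing *bundles* metadata/companion file."""


class TractogramIntegrityError(BundlesFormatError):
    """Declared curves_count disagrees with the decodable fiber payload."""


class AtlasFormatError(ValueError):
    """Atlas directory or atlas_info table violates the atlas contract."""


class MissingBundleError(AtlasFormatError):
    """A bundle listed in atlas_info has no fiber file in the atlas directory."""


@dataclass
class AtlasBundleEntry:
    """One named atlas fascicle: centroid fibers + segmentation threshold."""

    name: str
    threshold_mm: float
    size: int
    centroids: list[np.ndarray]  # each (21, 3)

    def __post_init__(self) -> None:
        if self.threshold_mm <= 0:
            raise AtlasFormatError(
                f"bundle {self.name!r}: threshold must be > 0, got {self.threshold_mm}")
        for c in self.centroids:
            if c.shape != (ATLAS_NPOINTS, 3):
                raise AtlasFormatError(
                    f"bundle {self.name!r}: centroid has {c.shape[0]} points, "
                    f"atlas centroids must have exactly {ATLAS_NPOINTS}")


@dataclass
class BundleAtlas:
    """Ordered list of atlas bundles (order = atlas_info order, used for ties)."""

    entries: list[AtlasBundleEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass
class DeformationField:
    """Voxel lattice of 3D world-mm displacement vectors with a voxel-to-world affine."""

    grid: np.ndarray  # (X, Y, Z, 3)
    affine: np.ndarray  # (4, 4)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.grid.ndim != 4 or self.grid.shape[-1] != 3:
            raise ValueError(f"deformation grid must be (X,Y,Z,3), got {self.grid.shape}")
        if any(s < 2 for s in self.grid.shape[:3]):
            raise ValueError("deformation grid needs >= 2 voxels per axis")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("voxel-to-world affine is not invertible")


# ---------------------------------------------------------------------------
# bundles / bundlesdata
# ---------------------------------------------------------------------------

_BYTE_ORDER_CODE = {"DCBA": "<", "ABCD": ">"}


def _data_path(bundles_path: Path, data_file_name: str) -> Path:
    name = data_file_name.replace("*", bundles_path.stem)
    return bundles_path.with_name(name)


def read_bundles(path: str | os.PathLike) -> Tractogram:
    """Read a ``*.bundles`` metadata file and its binary companion.

    Coordinates are preserved at 32-bit float precision; bundle label ranges
    are reconstructed from the metadata's (name, start_index) pairs.
    """
    path = Path(path)
    if not path.exists():
        raise BundlesFormatError(f"no such bundles file: {path}")
    text = path.read_text()
    brace = text.find("{")
    if brace < 0:
        raise BundlesFormatError(f"{path}: no attribute block found")
    try:
        attrs = ast.literal_eval(text[brace:])
    except (SyntaxError, ValueError) as exc:
        raise BundlesFormatError(f"{path}: unparsable attribute block: {exc}") from exc
    if not isinstance(attrs, dict):
        raise BundlesFormatError(f"{path}: attribute block is not a mapping")

    curves_count = int(attrs.get("curves_count", 0))
    byte_order = str(attrs.get("byte_order", "DCBA"))
    if byte_order not in _BYTE_ORDER_CODE:
        raise BundlesFormatError(f"{path}: unknown byte_order {byte_order!r}")
    endian = _BYTE_ORDER_CODE[byte_order]
    if int(attrs.get("space_dimension", 3)) != 3:
        raise BundlesFormatError(f"{path}: space_dimension must be 3")

    data_path = _data_path(path, str(attrs.get("data_file_name", "*.bundlesdata")))
    if not data_path.exists():
        raise BundlesFormatError(f"{path}: missing companion data file {data_path}")

    raw = np.frombuffer(data_path.read_bytes(), dtype=np.uint8)
    u32 = np.dtype(endian + "u4")
    f32 = np.dtype(endian + "f4")
    fibers: list[np.ndarray] = []
    off = 0
    total = raw.size
    while off < total:
        if off + 4 > total:
            raise TractogramIntegrityError(f"{data_path}: truncated point-count record")
        npts = int(raw[off:off + 4].view(u32)[0])
        off += 4
        nbytes = npts * 12
        if npts < 2 or off + nbytes > total:
            raise TractogramIntegrityError(
                f"{data_path}: fiber record at byte {off - 4} is invalid or truncated")
        pts = raw[off:off + nbytes].view(f32).reshape(npts, 3)
        fibers.append(pts.astype(np.float32))
        off += nbytes
    if len(fibers) != curves_count:
        raise TractogramIntegrityError(
            f"{path}: curves_count={curves_count} but decoded {len(fibers)} fibers")

    bundles = attrs.get("bundles", [])
    labels = None
    if bundles:
        labels = [(str(bundles[i]), int(bundles[i + 1]))
                  for i in range(0, len(bundles), 2)]
        starts = [s for _, s in labels]
        if starts[0] != 0 or any(b <= a for a, b in zip(starts, starts[1:])) \
                or any(s >= max(curves_count, 1) for s in starts):
            raise BundlesFormatError(f"{path}: invalid bundle label ranges {labels}")
    return Tractogram(fibers=fibers, labels=labels)


def write_bundles(tractogram: Tractogram, path: str | os.PathLike) -> None:
    """Write a tractogram as a ``*.bundles`` / ``*.bundlesdata`` pair (little-endian).

    An unlabeled tractogram gets a single default label covering all fibers.
    """
    if len(tractogram) == 0:
        raise ValueError("cannot write an empty tractogram")
    path = Path(path)
    if path.suffix != ".bundles":
        path = path.with_name(path.name + ".bundles")
    data_path = path.with_name(path.name + "data")

    labels = tractogram.labels or [("all", 0)]
    flat: list = []
    for name, start in labels:
        flat += [str(name), int(start)]
    attrs = {
        "binary": 1,
        "bundles": flat,
        "byte_order": "DCBA",
        "curves_count": len(tractogram),
        "data_file_name": "*.bundlesdata",
        "format": "bundles_1.0",
        "space_dimension": 3,
    }
    lines = ["attributes = {"]
    for key, val in attrs.items():
        lines.append(f"    {key!r} : {val!r},")
    lines.append("}\n")
    path.write_text("\n".join(lines))

    chunks = []
    for f in tractogram:
        f32 = np.ascontiguousarray(np.asarray(f, dtype=np.float32))
        chunks.append(np.asarray([f32.shape[0]], dtype="<u4").tobytes())
        chunks.append(f32.astype("<f4", copy=False).tobytes())
    data_path.write_bytes(b"".join(chunks))


# ---------------------------------------------------------------------------
# TRK / TCK conversion
# ---------------------------------------------------------------------------

_FORMATS = ("bundles", "trk", "tck")


def _read_any(path: Path, fmt: str) -> Tractogram:
    if fmt == "bundles":
        return read_bundles(path)
    if fmt in ("trk", "tck"):
        try:
            tf = nib.streamlines.load(str(path))  # points come out in world mm (RAS+)
        except Exception as exc:
            raise BundlesFormatError(f"{path}: cannot read as {fmt}: {exc}") from exc
        fibers = [np.asarray(s, dtype=np.float32) for s in tf.streamlines]
        return Tractogram(fibers=fibers)
    raise ValueError(f"unknown tractogram format {fmt!r}")


def _write_any(tractogram: Tractogram, path: Path, fmt: str) -> None:
    if fmt == "bundles":
        write_bundles(tractogram, path)
        return
    if fmt in ("trk", "tck"):
        nt = nib.streamlines.Tractogram(
            [np.asarray(f, dtype=np.float32) for f in tractogram],
            affine_to_rasmm=np.eye(4))
        nib.streamlines.save(nt, str(path))
        return
    raise ValueError(f"unknown tractogram format {fmt!r}")


def convert_tractogram(src: str | os.PathLike, dst: str | os.PathLike,
                       src_format: str, dst_format: str) -> None:
    """Convert between *bundles*, TRK and TCK, preserving world-mm coordinates.

    Fiber count and per-fiber point counts are preserved; coordinates round
    through 32-bit floats.  Identity conversion is an allowed copy.
    """
    if src_format not in _FORMATS or dst_format not in _FORMATS:
        raise ValueError(f"formats must be one of {_FORMATS}")
    t = _read_any(Path(src), src_format)
    _write_any(t, Path(dst), dst_format)


# ---------------------------------------------------------------------------
# deformation fields
# ---------------------------------------------------------------------------

def read_deformation_field(path: str | os.PathLike) -> DeformationField:
    """Load a NIfTI vector image (last dimension 3) as a displacement field."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 5 and data.shape[3] == 1:  # common (X,Y,Z,1,3) NIfTI layout
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"{path}: expected a vector image with last dimension 3, got shape {data.shape}")
    return DeformationField(grid=data, affine=np.asarray(img.affine))


def write_deformation_field(field: DeformationField, path: str | os.PathLike) -> None:
    """Write a displacement field as a NIfTI vector image."""
    img = nib.Nifti1Image(field.grid.astype(np.float32), field.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# atlases
# ---------------------------------------------------------------------------

def read_atlas(atlas_dir: str | os.PathLike, atlas_info: str | os.PathLike) -> BundleAtlas:
    """Load a bundle atlas: per-bundle fiber files + a name/threshold/size table.

    ``atlas_info`` has one bundle per line with whitespace-separated columns
    ``name threshold_mm size``; ``#`` lines are comments.  Every centroid fiber
    must have exactly 21 points (resampling is the caller's job).
    """
    atlas_dir = Path(atlas_dir)
    entries: list[AtlasBundleEntry] = []
    for lineno, line in enumerate(Path(atlas_info).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 3:
            raise AtlasFormatError(
                f"{atlas_info}:{lineno}: need columns name threshold_mm size")
        name, thr, size = cols[0], float(cols[1]), int(cols[2])
        if thr <= 0:
            raise AtlasFormatError(
                f"{atlas_info}:{lineno}: threshold must be > 0, got {thr}")
        fpath = atlas_dir / f"{name}.bundles"
        if not fpath.exists():
            raise MissingBundleError(
                f"bundle {name!r} listed in {atlas_info} but {fpath} does not exist")
        t = read_bundles(fpath)
        cents = [np.asarray(f, dtype=np.float64) for f in t]
        for c in cents:
            if c.shape[0] != ATLAS_NPOINTS:
                raise AtlasFormatError(
                    f"{fpath}: centroid with {c.shape[0]} points; atlas centroids "
                    f"must be sampled at {ATLAS_NPOINTS} equidistant points")
        entries.append(AtlasBundleEntry(name=name, threshold_mm=thr,
                                        size=size, centroids=cents))
    return BundleAtlas(entries=entries)


def write_atlas(atlas: BundleAtlas, atlas_dir: str | os.PathLike,
                atlas_info: str | os.PathLike) -> None:
    """Write a BundleAtlas as per-bundle files plus the atlas_info table."""
    atlas_dir = Path(atlas_dir)
    atlas_dir.mkdir(parents=True, exist_ok=True)
    lines = ["# name threshold_mm size"]
    for e in atlas:
        write_bundles(Tractogram(fibers=[c.astype(np.float32) for c in e.centroids],
                                 labels=[(e.name, 0)]),
                      atlas_dir / f"{e.name}.bundles")
        lines.append(f"{e.name} {e.threshold_mm:g} {e.size}")
    Path(atlas_info).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# bundles_id
# ---------------------------------------------------------------------------

def write_bundles_id(assignments: dict[str, list[int]], path: str | os.PathLike) -> None:
    """Write the per-group original-fiber-index table (one record per group).

    Each record is ``name: i1 i2 ...`` with ascending indices; empty groups
    produce a record with zero indices.
    """
    lines = []
    for name, idx in assignments.items():
        idx = sorted(int(i) for i in idx)
        lines.append(f"{name}: " + " ".join(str(i) for i in idx))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bundles_id(path: str | os.PathLike) -> dict[str, list[int]]:
    """Parse a bundles_id file back into the group -> indices mapping."""
    out: dict[str, list[int]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, _, rest = line.partition(":")
        out[name.strip()] = [int(tok) for tok in rest.split()]
    return out
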