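# Methods

This note documents the models and procedures implemented in tractokit, the
parameters that matter, the synthetic phantoms the test suite runs on, and the
numerical and design choices made where the design was genuinely open.

## Data model

A fiber is an ordered 3D polyline in world millimeters, stored as an
`(n_points, 3)` float array with `n_points >= 2`; a tractogram is an ordered
fiber list with optional contiguous bundle labeling (`(name, start_index)`
pairs partitioning the index range). All algorithms operate in world mm; TRK
voxel-ordered coordinates are mapped through the header affine (with the
half-voxel origin shift of that standard) on read, and TCK coordinates are
world mm already, so a single coordinate convention holds in memory.

The native *bundles* dialect writes, per fiber, one little-endian uint32
point count followed by `n_points` interleaved x,y,z float32 values; the text
metadata file carries the fiber count, byte order, and the flat
name/start-index label list. Big-endian files are read; output is always
little-endian. The per-fiber point-count record (rather than fixed-size
records) is the layout choice; it supports variable point counts, which the
whole toolkit accepts.

## The fiber distance

All comparisons use the maximum corresponding-point Euclidean distance
minimized over the direct and reversed point order of the second fiber
(`d_ME`). It is a metric-like similarity on equal-length fibers: symmetric,
non-negative, zero iff one ordering matches exactly, and invariant under
simultaneous rigid motion. The reversed branch handles tractography's
arbitrary seed-to-target orientation. The subscript convention is the full
point reversal `b_(N_p), ..., b_1`.

`dme_with_cutoff` adds per-branch early abandon: a branch stops as soon as
its running maximum exceeds the cutoff, and the sentinel `EXCEEDS` (infinity)
is returned only when both branches exceed it; any numeric return equals the
plain distance exactly. This is what lets segmentation discard far fibers
cheaply.

Resampling to a common point count places points at uniform arc-length
positions `k*L/(n-1)` along the polyline, linearly interpolated within
segments; endpoints are preserved exactly and zero-length segments contribute
zero arc length. Note that on a jagged polyline the *Euclidean chords*
between consecutive resampled points are not equal — equality holds for the
arc-length steps that generate the points; the tests assert the latter via an
independent segment-walking oracle.

## Atlas segmentation (fiberseg)

A bundle atlas is an ordered list of named entries, each holding 21-point
centroid fibers and a distance threshold in mm (the atlas table syntax is one
bundle per line: `name threshold_mm size`). Subject fibers are resampled to
21 points for comparison only; each fiber is assigned to the bundle owning
the *globally* closest centroid, provided the distance is within that
bundle's threshold, else left unassigned. Choices made here:

- Global argmin over all centroids (not per-bundle minima first); with a tie,
  the bundle listed first in the atlas table wins (`argmin` over centroids
  stacked in table order). Deterministic and order-stable.
- Single assignment only: a fiber within threshold of several bundles joins
  only the closest one.
- Thresholds are per-bundle and overridable at call time, since appropriate
  values depend on the dataset.
- Output keeps the original (un-resampled) fiber geometry; per-bundle
  centroids of the result are orientation-aligned pointwise means of the
  assigned fibers at 21 points.

The per-fiber computation is pure, so results are independent of any
parallel scheduling of the fiber loop.

## Hierarchical clustering (hclust)

Parameters (mm): `fiber_thr` = 30 (maximum distance for an affinity-graph
edge), `partition_thr` = 40 (adaptive partition threshold), `variance`
σ = 60 (similarity scale). The full pairwise d_ME matrix is computed at 21
points per fiber, edges kept where `d < fiber_thr`, and the affinity is
`a_ij = exp(-d_ij/σ²)` — implemented exactly in this form; the squared-
distance Gaussian kernel variant is available behind
`HClustParams.squared_affinity` for users who expect that convention.

Average-link agglomeration runs over the thresholded graph: the candidate
pairs are clusters connected by at least one edge, the merge score is the
mean pairwise *affinity* over all cross pairs (maximized), and clusters in
different graph components never merge, so the result is a forest with
isolated fibers as singleton roots. Because the exponential is nonlinear,
maximizing mean affinity differs from minimizing mean distance; the
distance-linkage variant is switchable (`linkage="distance"`). Ties on the
merge score break toward the lexicographically smallest pair of minimum leaf
indices, making the whole construction deterministic.

Each merge node records the maximum intra-member pairwise distance
(non-decreasing toward the root). The adaptive partition walks each tree from
the root and accepts a node as a cluster at the shallowest depth where that
maximum is at most `partition_thr`; leaves always terminate, so the clusters
partition the fibers, and every produced cluster provably satisfies the
intra-distance bound.

The O(n²) distance matrix is the scaling limit; a warning is emitted above
40,000 fibers. The recommended recipe for larger data is fast clustering
first, then hierarchical clustering of the resulting centroids (documented
here as a recipe, not an operation).

## Fast clustering (ffclust)

Four stages over fibers resampled to 21 points:

1. **Point K-Means.** Independent MiniBatch K-Means on the 3D coordinates of
   selected points (defaults 0, 3, 10, 17, 20) with per-point cluster counts
   (defaults 300, 200, 200, 200, 300), k-means++ initialization, 100
   iterations, batch size 10% of the fiber count capped at 10,000, seeded
   `seed + point_position`. K-Means specifics are configurable; a cluster
   count above the fiber count clamps with a warning.
2. **Map clustering.** Fibers sharing the identical label tuple across the
   selected points form one preliminary cluster. Tuples are not matched
   against their reversals; orientation is handled by d_ME in stages 3–4.
3. **Reassignment.** Every fiber of a cluster at or below
   `small_cluster_max_size` (default 5 — map clustering produces many
   near-singleton tuples, and this stage exists to absorb them) is compared
   to the centroids of all larger clusters, computed once before any move;
   it moves to the nearest large cluster when within `assign_thr` (6 mm).
   One pass, no cascading, per-fiber moves: deterministic and independent of
   enumeration order; large clusters never shrink.
4. **Merge.** Candidate pairs share the Stage-1 label at the central
   selected point — defined as the middle entry of the point list (point 10
   of 21 under defaults). Candidates whose centroids are within `join_thr`
   (6 mm) merge transitively via union-find; merged centroids are
   recomputed.

The pipeline partitions the input after every stage and is reproducible
under its seed. By construction it prefers oversegmentation: two clusters
merge only if they agree on the central-point K-Means cell *and* have close
centroids. On synthetic phantoms whose bundles are tight blobs (per-point
spread ~1 mm) this is a strong limitation: K-Means with k in the hundreds
subdivides each blob into many cells, map tuples become near-unique, and the
central-label condition prevents fragments of one bundle from merging, so
the final clustering refines the true bundles into many clusters (adjusted
Rand index ~0.1 against ground truth on a 10-bundle, 20,000-fiber phantom)
while still never fusing well-separated bundles — the property the tests
assert. On real whole-brain tractograms the point clouds are far more
dispersed relative to the cell size, which is the regime the stage structure
is designed for; the phantom result is a faithful picture of the algorithm's
oversegmentation bias at phantom scale, not of an implementation defect.

## Utilities

**Deform.** Displacement fields are voxel grids of 3-vectors (NIfTI; 4D
`(X,Y,Z,3)` or the common `(X,Y,Z,1,3)` layout) with a voxel-to-world
affine. Each point maps through the inverse affine to voxel coordinates, the
vector is trilinearly interpolated, and the displacement is added in world
mm. Trilinear interpolation is exact for affine fields, which the tests
exploit (a field sampling `x -> Ax + t` reproduces the closed form to
1e-4 mm). Points outside the grid take the nearest-edge voxel's value
(clamped) and the clamp count is logged — dropping points would change fiber
topology. Dense coordinate maps (absolute target positions rather than
displacements) are supported via `mode="absolute"`, since published warp
files come in both conventions.

**Intersection.** Both sets resampled to a common 21 points; a fiber of one
set is matched if its nearest d_ME in the other set is within the threshold;
the two percentages (0–100) are reported in argument order. Monotone in the
threshold; components swap under argument swap.

**Metrics.** One row per bundle file: size, mean polyline length over
original geometry, and maximum pairwise d_ME at 21 points (0 for singleton
bundles), as a pandas DataFrame keyed by file stem; unreadable files are
skipped with a logged warning so one corrupt file does not kill a batch.
Filtering applies closed numeric ranges (open bounds allowed) that must all
hold; an inverted range is an error.

## ROI dissection

The octree stores every fiber point; a node splits into its eight octants
when its capacity (default 64) overflows, except at the maximum depth (12),
where overflow is allowed so coincident points cannot recurse forever.
Sphere queries prune nodes by the closest-point-on-box distance, accept
whole subtrees whose boxes lie inside the sphere (all eight corners within
the radius) without per-point tests, and test points only in colliding
leaves; the result is exactly the set of fibers with at least one point in
the sphere, verified against brute-force scans. Selections combine with
`& | ^ !` and parentheses over ROI ids (precedence `!` > `&` > `^` > `|`),
NOT complementing against the full fiber universe.

## Phantoms

The generator emulates the geometry that matters to these algorithms:
multiple spatially separated bundles of noisy polylines with known labels.
Four backbone families (line, circular arc, U-shape with straight legs,
helix) cover straight, curved, arcuate-like and twisting trajectories. Each
fiber samples its backbone at a per-fiber random point count (exercising
variable-point-count handling), adds i.i.d. per-point Gaussian offsets whose
tangential component is attenuated to 30% (dispersion in a tract is mostly
perpendicular to it), and is stored reversed with probability one half to
exercise orientation handling. Default conditions used by the tests: jitter
sd 0.5–1 mm, 60–2,000 fibers per bundle, backbone separations tens of mm —
chosen to mirror the tight, well-separated fascicle geometry of real deep
white matter at a desk-testable scale. The derived atlas uses the 21-point
backbones as centroids with threshold `threshold_factor * jitter_sd`
(default factor 3).

What the phantoms do *not* emulate: crossing/kissing bundle configurations,
fiber-density gradients, length-dependent truncation, scanner noise, and
anatomically realistic trajectories. Passing tests therefore demonstrate
algorithmic correctness (oracle equivalence, invariants, recovery under
separation), not segmentation quality on real brains.

A note on thresholds versus jitter: the d_ME from a generated fiber to its
backbone is the maximum over 21 points of a ~2-dof Gaussian norm, so it
concentrates around 2–3 jitter sd with a tail bounded in practice by 6 sd.
An atlas threshold of 3 sd therefore leaves a substantial fraction of fibers
(~15%) unassigned, while 6 sd recovers 100% — both numbers are computed by
the acceptance script (`fiberseg_recovery_pct_3sigma`,
`fiberseg_recovery_pct_6sigma`).

## Numerical choices and degenerate inputs

- Distances and resampling run in float64; file coordinates are float32 (the
  format's precision), so round trips are bit-exact in float32.
- Resampling a degenerate fiber whose points all coincide returns copies of
  that point; zero-length segments elsewhere are tolerated.
- `bundle_centroid` aligns every fiber to the *first* member (flip when the
  reversed order is closer) and averages pointwise; a medoid mode (member
  minimizing summed d_ME) is available. The mean is the default because
  atlas centroids behave as representative trajectories, not members.
- All stochastic components (phantoms, MiniBatch K-Means) are seeded;
  identical seeds give identical outputs run-to-run.
- Problem sizes in the tests — up to 1,000 fibers for octree/format checks,
  50 fibers for the O(n³) hierarchical oracle, 20,000 fibers for the fast
  clustering pipeline — are chosen so every oracle comparison is exhaustive
  at a scale a laptop handles in seconds.

## Known limitations

- TRK scalar/property payloads are skipped on read, not preserved.
- hclust's dense distance matrix bounds practical input size (warning above
  40,000 fibers).
- ffclust's oversegmentation on tight phantom bundles, discussed above.
- No mesh/GIfTI I/O, no registration (deformation fields are inputs), no
  diffusion-metric sampling along fibers, no rendering.
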