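"""Headless virtual dissection: an octree over all fiber points, spherical-ROI
queries, and a boolean selection algebra over ROI hit sets.

The octree stores every point of every fiber; a node whose capacity overflows
splits its bounding box into the eight octants (overflow is allowed at the
maximum depth so coincident points cannot recurse forever).  A sphere query
prunes nodes disjoint from the sphere (closest-point-on-box test), takes whole
subtrees whose boxes lie entirely inside the sphere (all eight corners within
the radius) without per-point tests, and tests points individually in
colliding leaves; it returns the set of fiber indices with at least one point
inside the sphere.  Selections from several ROIs combine with AND/OR/XOR/NOT
(``&``, ``|``, ``^``, ``!``) over fiber-index sets, NOT complementing against
the full fiber universe — e.g. ``"0&1&!2"`` keeps fibers touching ROIs 0 and 1
but not ROI 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Tractogram

__all__ = ["SphereROI", "Octree", "build_octree", "query_sphere",
           "select_by_expression", "ExpressionError", "dissect"]

MAX_DEPTH = 12


@dataclass
class SphereROI:
    """Spherical region of interest (world mm)."""

    id: int
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


class _Node:
    __slots__ = ("lo", "hi", "box_min", "box_max", "children")

    def __init__(self, lo: int, hi: int, box_min, box_max):
        self.lo = lo          # slice into the permuted point array
        self.hi = hi
        self.box_min = box_min
        self.box_max = box_max
        self.children: list["_Node"] | None = None


class Octree:
    """Point octree over a tractogram; nodes hold slices of a permuted array.

    ``capacity`` is the leaf point budget (leaves may exceed it only at the
    maximum depth).  Build order is deterministic given input order.
    """

    def __init__(self, tractogram: Tractogram, capacity: int = 64,
                 max_depth: int = MAX_DEPTH):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        if len(tractogram) == 0:
            raise ValueError("cannot build an octree over an empty tractogram")
        pts = np.concatenate([np.asarray(f, dtype=np.float64) for f in tractogram])
        fiber_ids = np.concatenate([np.full(len(f), i, dtype=np.int64)
                                    for i, f in enumerate(tractogram)])
        point_ids = np.concatenate([np.arange(len(f), dtype=np.int64)
                                    for f in tractogram])
        self.capacity = capacity
        self.max_depth = max_depth
        self.n_fibers = len(tractogram)
        self.perm = np.arange(len(pts))
        self.points = pts
        self.fiber_ids = fiber_ids
        self.point_ids = point_ids
        self.root = self._build(0, len(pts), pts.min(axis=0), pts.max(axis=0), 0)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def _build(self, lo: int, hi: int, box_min, box_max, depth: int) -> _Node:
        node = _Node(lo, hi, box_min, box_max)
        if hi - lo <= self.capacity or depth >= self.max_depth:
            return node
        mid = (box_min + box_max) / 2.0
        idx = self.perm[lo:hi]
        pts = self.points[idx]
        octant = ((pts[:, 0] > mid[0]).astype(np.int8)
                  | ((pts[:, 1] > mid[1]).astype(np.int8) << 1)
                  | ((pts[:, 2] > mid[2]).astype(np.int8) << 2))
        order = np.argsort(octant, kind="stable")
        self.perm[lo:hi] = idx[order]
        octant_sorted = octant[order]
        bounds = np.searchsorted(octant_sorted, np.arange(9))
        node.children = []
        for o in range(8):
            a, b = lo + bounds[o], lo + bounds[o + 1]
            cmin = np.where([o & 1, o & 2, o & 4], mid, box_min)
            cmax = np.where([o & 1, o & 2, o & 4], box_max, mid)
            node.children.append(self._build(a, b, cmin, cmax, depth + 1))
        return node

    def leaf_sizes(self) -> list[int]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            if n.children is None:
                out.append(n.hi - n.lo)
            else:
                stack.extend(n.children)
        return out

    def depth_of_leaves(self) -> list[int]:
        out, stack = [], [(self.root, 0)]
        while stack:
            n, d = stack.pop()
            if n.children is None:
                out.append(d)
            else:
                stack.extend((c, d + 1) for c in n.children)
        return out


def build_octree(tractogram: Tractogram, capacity: int = 64) -> Octree:
    """Build a point octree over every fiber point (tight bounding box)."""
    return Octree(tractogram, capacity=capacity)


def query_sphere(tree: Octree, roi: SphereROI) -> set[int]:
    """Fiber indices with at least one point within ``roi.radius`` of its center."""
    center = np.asarray(roi.center, dtype=np.float64)
    r2 = roi.radius * roi.radius
    hit: set[int] = set()
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node.hi == node.lo:
            continue
        # closest point of the box to the sphere center: prune disjoint nodes
        closest = np.clip(center, node.box_min, node.box_max)
        if ((closest - center) ** 2).sum() > r2:
            continue
        # box fully inside the sphere: take all fibers, no per-point tests
        corners = np.array([[node.box_min[d] if (o >> d) & 1 == 0 else node.box_max[d]
                             for d in range(3)] for o in range(8)])
        if (((corners - center) ** 2).sum(axis=1) <= r2).all():
            hit.update(tree.fiber_ids[tree.perm[node.lo:node.hi]].tolist())
            continue
        if node.children is not None:
            stack.extend(node.children)
        else:
            idx = tree.perm[node.lo:node.hi]
            d2 = ((tree.points[idx] - center) ** 2).sum(axis=1)
            hit.update(tree.fiber_ids[idx[d2 <= r2]].tolist())
    return hit


class ExpressionError(ValueError):
    """Malformed ROI selection expression or unknown ROI id."""


class _Parser:
    """Recursive-descent parser for the ROI algebra.

    Grammar (loosest to tightest binding)::

        or   := xor ('|' xor)*
        xor  := and ('^' and)*
        and  := not ('&' not)*
        not  := '!' not | id | '(' or ')'
    """

    def __init__(self, expr: str, sets: dict[int, frozenset], universe: frozenset):
        self.tokens = self._tokenize(expr)
        self.pos = 0
        self.sets = sets
        self.universe = universe

    @staticmethod
    def _tokenize(expr: str) -> list[str]:
        tokens, i = [], 0
        while i < len(expr):
            c = expr[i]
            if c.isspace():
                i += 1
            elif c in "&|^!()":
                tokens.append(c)
                i += 1
            elif c.isdigit():
                j = i
                while j < len(expr) and expr[j].isdigit():
                    j += 1
                tokens.append(expr[i:j])
                i = j
            else:
                raise ExpressionError(f"unexpected character {c!r} in expression")
        return tokens

    def _peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise ExpressionError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> frozenset:
        out = self._or()
        if self._peek() is not None:
            raise ExpressionError(f"trailing token {self._peek()!r}")
        return out

    def _or(self) -> frozenset:
        out = self._xor()
        while self._peek() == "|":
            self._next()
            out = out | self._xor()
        return out

    def _xor(self) -> frozenset:
        out = self._and()
        while self._peek() == "^":
            self._next()
            out = out ^ self._and()
        return out

    def _and(self) -> frozenset:
        out = self._not()
        while self._peek() == "&":
            self._next()
            out = out & self._not()
        return out

    def _not(self) -> frozenset:
        tok = self._next()
        if tok == "!":
            return self.universe - self._not()
        if tok == "(":
            out = self._or()
            if self._next() != ")":
                raise ExpressionError("missing closing parenthesis")
            return out
        if tok.isdigit():
            rid = int(tok)
            if rid not in self.sets:
                raise ExpressionError(f"unknown ROI id {rid}")
            return self.sets[rid]
        raise ExpressionError(f"unexpected token {tok!r}")


def select_by_expression(per_roi_sets: dict[int, set[int]], expr: str,
                         universe: int) -> set[int]:
    """Evaluate a boolean ROI expression over fiber-index sets.

    ``universe`` is the tractogram fiber count; NOT complements against
    ``{0, ..., universe-1}``.
    """
    sets = {int(k): frozenset(v) for k, v in per_roi_sets.items()}
    uni = frozenset(range(universe))
    return set(_Parser(expr, sets, uni).parse())


def dissect(tractogram: Tractogram, rois: list[SphereROI], expr: str,
            capacity: int = 64) -> set[int]:
    """Virtual dissection: octree + per-ROI sphere queries + boolean selection."""
    tree = build_octree(tractogram, capacity=capacity)
    per_roi = {roi.id: query_sphere(tree, roi) for roi in rois}
    return select_by_expression(per_roi, expr, len(tractogram))
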