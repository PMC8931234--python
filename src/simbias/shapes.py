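"""Free-polyomino canonicalization, symmetry classification and enumeration.

A polyomino phenotype is an edge-connected set of unit cells considered up to
translation, rotation and reflection (a *free* polyomino).  Its symmetry
class is the conjugacy class of the subgroup of the order-8 dihedral group of
the square that fixes the shape up to translation: C1 (asymmetric), C2, C4
(rotations only), D1, D2 (with mirrors) and D4 (all eight transforms).

Enumeration comes in three flavors:

* :func:`free_shapes` — explicit growth enumeration with canonical
  deduplication; practical up to n ≈ 12.
* :func:`enumerate_free` — exact counts for any n via Redelmeier counting of
  fixed polyominoes plus a Burnside correction whose symmetric terms are
  produced by :func:`enumerate_invariant`-style orbit construction.
* :func:`enumerate_invariant` — shapes whose stabilizer contains a given
  group, built directly as connected unions of symmetry orbits around
  cell-centered and vertex-centered symmetry centers.  This makes the
  high-symmetry tail of large morphospaces (e.g. all fourfold-symmetric
  16-mers) accessible without enumerating the full space.

Internally symmetry centers live on the *doubled* lattice: a cell (x, y)
sits at doubled point (2x, 2y), so cell centers are even/even points,
lattice vertices odd/odd and edge midpoints mixed-parity points.  Fourfold
rotation centers must have equal parities; twofold centers may be any of the
three kinds.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from ._kernels import _count_fixed


class BudgetError(ValueError):
    """Requested enumeration exceeds the configured size budget."""


class DisconnectedShapeError(ValueError):
    """Cell set is not edge-connected."""


# the 8 transforms of the square dihedral group, index-aligned with _kernels
_TRANSFORMS = (
    lambda x, y: (x, y),
    lambda x, y: (y, -x),
    lambda x, y: (-x, -y),
    lambda x, y: (-y, x),
    lambda x, y: (-x, y),
    lambda x, y: (x, -y),
    lambda x, y: (y, x),
    lambda x, y: (-y, -x),
)
_IDX_R90 = 1
_IDX_R180 = 2
_IDX_R270 = 3
_IDX_MY = 4  # (-x, y)
_IDX_MX = 5  # (x, -y)
_IDX_D1 = 6  # (y, x)
_IDX_D2 = 7  # (-y, -x)


@dataclass(frozen=True)
class SymmetryClass:
    """Conjugacy class of a shape's stabilizer subgroup.

    ``label`` is one of C1, C2, C4, D1, D2, D4; ``flavor`` distinguishes the
    axis-aligned and diagonal realizations of D1/D2 (None otherwise).
    Reports collapse flavors into the bare label; the flavor is metadata.
    """

    label: str
    flavor: str | None = None

    def __str__(self) -> str:
        return self.label


def _as_cells(cells) -> frozenset:
    if hasattr(cells, "cells"):
        cells = cells.cells
    out = frozenset((int(x), int(y)) for x, y in cells)
    if not out:
        raise ValueError("empty cell set")
    return out


def _is_connected(cells: frozenset) -> bool:
    start = next(iter(cells))
    seen = {start}
    stack = [start]
    while stack:
        x, y = stack.pop()
        for nb in ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1)):
            if nb in cells and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(cells)


def _normalize(cells) -> tuple:
    pts = list(cells)
    minx = min(x for x, _ in pts)
    miny = min(y for _, y in pts)
    return tuple(sorted((x - minx, y - miny) for x, y in pts))


def canonical_form(cells) -> tuple:
    """Canonical free-polyomino form of an edge-connected cell set.

    Translated so minimal coordinates are zero and lexicographically minimal
    over the 8 square-dihedral transforms; idempotent.
    """
    cset = _as_cells(cells)
    if not _is_connected(cset):
        raise DisconnectedShapeError(f"cell set of size {len(cset)} is not "
                                     "edge-connected")
    return min(_normalize(tf(x, y) for x, y in cset) for tf in _TRANSFORMS)


@dataclass(frozen=True)
class Shape:
    """A bounded polyomino phenotype (canonical free form)."""

    cells: tuple
    canonical: bool = True

    @property
    def size(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def __len__(self):
        return len(self.cells)


def stabilizer(cells) -> frozenset:
    """Indices (into the 8 dihedral transforms) fixing the shape up to
    translation."""
    cset = _as_cells(cells)
    base = _normalize(cset)
    return frozenset(
        i for i, tf in enumerate(_TRANSFORMS)
        if _normalize(tf(x, y) for x, y in cset) == base)


def symmetry_class(cells) -> SymmetryClass:
    """Symmetry class of a shape, from its stabilizer subgroup."""
    stab = stabilizer(cells)
    order = len(stab)
    if order == 8:
        return SymmetryClass("D4")
    if order == 4:
        if _IDX_R90 in stab:
            return SymmetryClass("C4")
        if _IDX_MX in stab or _IDX_MY in stab:
            return SymmetryClass("D2", "axis")
        return SymmetryClass("D2", "diagonal")
    if order == 2:
        if _IDX_R180 in stab:
            return SymmetryClass("C2")
        if _IDX_MX in stab or _IDX_MY in stab:
            return SymmetryClass("D1", "axis")
        return SymmetryClass("D1", "diagonal")
    return SymmetryClass("C1")


# ---------------------------------------------------------------------------
# growth enumeration (explicit shapes, small n)

_GROWTH_BUDGET = 12


@lru_cache(maxsize=None)
def _free_shape_set(n: int) -> frozenset:
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > _GROWTH_BUDGET:
        raise BudgetError(f"explicit enumeration is limited to n <= "
                          f"{_GROWTH_BUDGET}; use enumerate_free or "
                          f"enumerate_invariant for larger n")
    shapes = {((0, 0),)}
    for _ in range(n - 1):
        grown = set()
        for shape in shapes:
            cset = set(shape)
            for x, y in shape:
                for nb in ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1)):
                    if nb not in cset:
                        grown.add(canonical_form(cset | {nb}))
        shapes = grown
    return frozenset(shapes)


def free_shapes(n: int):
    """Iterate all free n-ominoes in canonical form (growth enumeration)."""
    yield from sorted(_free_shape_set(n))


# ---------------------------------------------------------------------------
# invariant-shape enumeration by symmetry-orbit construction

# doubled-lattice matrices (a, b, c, d): (x, y) -> (a x + b y, c x + d y)
_M_R90 = (0, 1, -1, 0)
_M_R180 = (-1, 0, 0, -1)
_M_R270 = (0, -1, 1, 0)
_M_MX = (1, 0, 0, -1)
_M_MY = (-1, 0, 0, 1)
_M_D1 = (0, 1, 1, 0)
_M_D2 = (0, -1, -1, 0)

_CENTERS_POINT_ALL = ((0, 0), (1, 1), (1, 0), (0, 1))
_CENTERS_EQ_PARITY = ((0, 0), (1, 1))

# group label -> (non-identity elements, centers, rooting mode)
_GROUP_DEFS = {
    ("C4", None): ((_M_R90, _M_R180, _M_R270), _CENTERS_EQ_PARITY, "point"),
    ("D4", None): ((_M_R90, _M_R180, _M_R270, _M_MX, _M_MY, _M_D1, _M_D2),
                   _CENTERS_EQ_PARITY, "point"),
    ("C2", None): ((_M_R180,), _CENTERS_POINT_ALL, "point"),
    ("D2", "axis"): ((_M_R180, _M_MX, _M_MY), _CENTERS_POINT_ALL, "point"),
    ("D2", "diagonal"): ((_M_R180, _M_D1, _M_D2), _CENTERS_EQ_PARITY,
                         "point"),
    ("D1", "axis"): ((_M_MX,), ((0, 0), (0, 1)), "line-x"),
    ("D1", "diagonal"): ((_M_D1,), ((0, 0),), "line-diag"),
}


def _apply(mat, cx, cy, x, y):
    a, b, c, d = mat
    dx, dy = x - cx, y - cy
    return cx + a * dx + b * dy, cy + c * dx + d * dy


def _connected_orbit_unions(orbits, adj, sizes, n, roots):
    """Unions of orbits, connected in the orbit-adjacency graph, of total
    cell count exactly n, enumerated once each (min-indexed-orbit rooting)."""
    results = []
    N = len(orbits)
    seen = bytearray(N)
    cur = []

    def rec(size, ext):
        for i in range(len(ext)):
            o = ext[i]
            ns = size + sizes[o]
            if ns > n:
                continue
            cur.append(o)
            if ns == n:
                results.append(tuple(cur))
            else:
                add = [q for q in adj[o] if not seen[q]]
                for q in add:
                    seen[q] = 1
                rec(ns, ext[i + 1:] + add)
                for q in add:
                    seen[q] = 0
            cur.pop()

    for r in roots:
        for q in range(N):
            seen[q] = 1 if q <= r else 0
        cur.append(r)
        if sizes[r] == n:
            results.append(tuple(cur))
        else:
            ext0 = [q for q in adj[r] if not seen[q]]
            for q in ext0:
                seen[q] = 1
            rec(sizes[r], ext0)
        cur.pop()
    return results


def _invariant_cellsets(n: int, mats, centers, mode: str) -> set:
    """Translation-normalized cell sets (regular coordinates) of size n
    invariant under the group generated by ``mats`` about some center of the
    given parity classes.  Connectivity is checked at cell level."""
    found = set()
    for cx, cy in centers:
        # doubled-lattice universe of candidate cells
        if mode == "point":
            rad = 2 * n + 8
            cells = [(x, y)
                     for x in range(cx - rad - 1, cx + rad + 2)
                     for y in range(cy - rad - 1, cy + rad + 2)
                     if x % 2 == 0 and y % 2 == 0]
        elif mode == "line-x":
            rad = 2 * n + 4
            cells = [(x, y)
                     for x in range(0, 2 * n + 1, 2)
                     for y in range(cy - rad, cy + rad + 1)
                     if y % 2 == 0]
        elif mode == "line-diag":
            rad = 2 * n + 4
            cells = [(x, y)
                     for x in range(-rad, rad + 1, 2)
                     for y in range(-rad, rad + 1, 2)
                     if 0 <= x + y <= 4 * n]
        else:  # pragma: no cover
            raise ValueError(mode)
        universe = set(cells)
        orbit_of = {}
        orbit_list = []
        for cell in cells:
            if cell in orbit_of:
                continue
            orb = {cell}
            for mat in mats:
                orb.add(_apply(mat, cx, cy, *cell))
            if not orb <= universe:
                continue
            orb = frozenset(orb)
            if len(orb) > n:
                continue
            idx = len(orbit_list)
            orbit_list.append(orb)
            for p in orb:
                orbit_of[p] = idx
        # deterministic ordering by representative
        if mode == "line-diag":
            rep = [min((x + y, x - y) for x, y in orb) for orb in orbit_list]
        else:
            rep = [min(orb) for orb in orbit_list]
        order = sorted(range(len(orbit_list)), key=lambda i: rep[i])
        orbit_list = [orbit_list[i] for i in order]
        rep = [rep[i] for i in order]
        orbit_of = {p: i for i, orb in enumerate(orbit_list) for p in orb}
        sizes = [len(orb) for orb in orbit_list]
        adj = []
        for orb in orbit_list:
            nbrs = set()
            for x, y in orb:
                for nb in ((x + 2, y), (x - 2, y), (x, y + 2), (x, y - 2)):
                    j = orbit_of.get(nb)
                    if j is not None:
                        nbrs.add(j)
            adj.append(sorted(nbrs - {orbit_of[next(iter(orb))]}))
        if mode == "point":
            roots = list(range(len(orbit_list)))
        elif mode == "line-x":
            roots = [i for i, orb in enumerate(orbit_list)
                     if min(x for x, _ in orb) == 0]
        else:
            roots = [i for i, r in enumerate(rep) if r[0] in (0, 2)]
        for union in _connected_orbit_unions(orbit_list, adj, sizes, n,
                                             roots):
            pts = set()
            for idx in union:
                pts |= orbit_list[idx]
            cellset = frozenset(((x // 2), (y // 2)) for x, y in pts)
            if len(cellset) != n or not _is_connected(cellset):
                continue
            found.add(frozenset(_normalize(cellset)))
    return found


def enumerate_invariant(n: int, group: str, flavor: str | None = None) -> set:
    """All free n-ominoes whose stabilizer *contains* the given group.

    ``group`` is one of C4, D4, C2, D2, D1; D1/D2 accept an optional
    ``flavor`` ("axis" or "diagonal"), defaulting to the union of both.
    Shapes are returned as canonical-form cell tuples.
    """
    group = group.upper()
    if group in ("C4", "D4", "C2"):
        defs = [(group, None)]
    elif group in ("D1", "D2"):
        if flavor is None:
            defs = [(group, "axis"), (group, "diagonal")]
        elif flavor in ("axis", "diagonal"):
            defs = [(group, flavor)]
        else:
            raise ValueError(f"unknown flavor {flavor!r}")
    else:
        raise ValueError(f"unsupported group {group!r}")
    out = set()
    for key in defs:
        mats, centers, mode = _GROUP_DEFS[key]
        for cellset in _invariant_cellsets(n, mats, centers, mode):
            out.add(canonical_form(cellset))
    return out


# ---------------------------------------------------------------------------
# counting

@lru_cache(maxsize=None)
def fixed_counts(n: int) -> tuple:
    """Numbers of fixed (translation-only) polyominoes of sizes 1..n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return tuple(int(v) for v in _count_fixed(n)[1:])


@lru_cache(maxsize=None)
def _invariant_class_count(n: int, element: str) -> int:
    """Translation classes of fixed n-ominoes invariant under one transform
    (any compatible center), for the Burnside free-count correction."""
    if element == "r90":
        mats, centers, mode = (_M_R90, _M_R180, _M_R270), _CENTERS_EQ_PARITY, \
            "point"
    elif element == "r180":
        mats, centers, mode = (_M_R180,), _CENTERS_POINT_ALL, "point"
    elif element == "mirror":
        mats, centers, mode = (_M_MX,), ((0, 0), (0, 1)), "line-x"
    elif element == "diagonal":
        mats, centers, mode = (_M_D1,), ((0, 0),), "line-diag"
    else:  # pragma: no cover
        raise ValueError(element)
    return len(_invariant_cellsets(n, mats, centers, mode))


@lru_cache(maxsize=None)
def enumerate_free(n: int) -> int:
    """Number of distinct free polyominoes with exactly n cells.

    Burnside's lemma over the dihedral group of the square: the average of
    fixed-polyomino counts invariant under each of the 8 transforms.  The
    identity term comes from Redelmeier counting; the 7 symmetric terms from
    orbit construction, which is cheap because symmetric shapes are rare.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    fixed = fixed_counts(n)[n - 1]
    total = (fixed
             + 2 * _invariant_class_count(n, "r90")
             + _invariant_class_count(n, "r180")
             + 2 * _invariant_class_count(n, "mirror")
             + 2 * _invariant_class_count(n, "diagonal"))
    assert total % 8 == 0, "Burnside sum must be divisible by the group order"
    return total // 8


_CLASS_LABELS = ("C1", "C2", "C4", "D1", "D2", "D4")


def count_symmetry_classes(n: int) -> dict:
    """Tally of free n-ominoes per symmetry class; values sum to
    enumerate_free(n).

    Small n classifies the explicit enumeration; large n enumerates only the
    symmetric shapes (every nontrivial stabilizer contains a twofold rotation
    or a mirror) and obtains C1 by subtraction from the Burnside total.
    """
    counts = {label: 0 for label in _CLASS_LABELS}
    if n <= 10:
        for shape in _free_shape_set(n):
            counts[symmetry_class(shape).label] += 1
        return counts
    symmetric = (enumerate_invariant(n, "C2")
                 | enumerate_invariant(n, "D1"))
    for shape in symmetric:
        counts[symmetry_class(shape).label] += 1
    counts["C1"] = enumerate_free(n) - sum(
        counts[lbl] for lbl in _CLASS_LABELS if lbl != "C1")
    return counts
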