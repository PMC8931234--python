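"""Low-level self-assembly kernels.

The lattice self-assembly loop is the hot path of every analysis in this
package (a single frequency estimate may run tens of millions of assembly
trials), so the inner loops live here in a restricted, array-only style that
numba can compile.  When numba is unavailable the identical functions run as
pure Python with the same semantics, only slower.

Conventions
-----------
* Edge order on a tile is (N, E, S, W); direction codes 0=N, 1=E, 2=S, 3=W.
* Orientation ``o`` rotates a tile by ``90*o`` degrees clockwise, so the
  color facing direction ``d`` is ``colors[(d - o) % 4]``.
* Interface colors bond in the unique pairs (1,2), (3,4), ... while color 0
  and the maximal color ``2**b - 1`` are neutral.
* Shapes are encoded as sorted int64 arrays of ``x * STRIDE + y`` with
  translation-normalized nonnegative coordinates; the encoding preserves the
  lexicographic order of ``(x, y)`` pairs.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every test run
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


#: stride of the (x, y) -> int64 cell encoding; coordinates must stay below it
STRIDE = 512

_DX = np.array([0, 1, 0, -1], dtype=np.int64)
_DY = np.array([1, 0, -1, 0], dtype=np.int64)


def make_partner_table(bits_per_color: int) -> np.ndarray:
    """Bonding partner for every color; -1 marks a neutral (non-bonding) color.

    Colors pair as (1, 2), (3, 4), ...; color 0 and the maximal color are
    neutral, so with ``b`` bits there are ``2**(b-1) - 1`` bonding pairs.
    """
    n_colors = 1 << bits_per_color
    partner = np.full(n_colors, -1, dtype=np.int64)
    for c in range(1, n_colors - 1):
        partner[c] = c + 1 if c % 2 == 1 else c - 1
    return partner


@njit(cache=True)
def _build_match(colors, n_colors, match_cnt, match_list):
    """Index (tile, orientation) pairs by the color they present per direction."""
    n_tiles = colors.shape[0]
    for c in range(n_colors):
        for d in range(4):
            match_cnt[c, d] = 0
    for t in range(n_tiles):
        for o in range(4):
            for d in range(4):
                c = colors[t, (d - o) % 4]
                k = match_cnt[c, d]
                match_list[c, d, k, 0] = t
                match_list[c, d, k, 1] = o
                match_cnt[c, d] = k + 1


@njit(cache=True)
def _assemble_trial(colors, partner, match_cnt, match_list, cutoff, G,
                    occ_stamp, occ_tile, occ_orient, seen, moves, cells,
                    stamp, seed_tile):
    """One stochastic assembly run from a single seed tile.

    ``seed_tile`` is the tile type placed first (orientation 0 at the grid
    center); -1 draws it uniformly at random.  Returns ``(status, ncells,
    branched)`` where status 0 means the structure terminated within the
    cutoff and 1 means it exceeded a cutoff x cutoff bounding box.
    ``branched`` records whether any step offered more than one available
    move (if not, the run was fully deterministic).
    """
    n_tiles = colors.shape[0]
    center = G // 2
    ncells = 0
    nm = 0
    minx = center
    maxx = center
    miny = center
    maxy = center
    branched = False
    x = center
    y = center
    t = seed_tile if seed_tile >= 0 else np.random.randint(n_tiles)
    o = 0
    while True:
        si = x * G + y
        occ_stamp[si] = stamp
        occ_tile[si] = t
        occ_orient[si] = o
        cells[ncells, 0] = x
        cells[ncells, 1] = y
        cells[ncells, 2] = t
        cells[ncells, 3] = o
        ncells += 1
        if x < minx:
            minx = x
        if x > maxx:
            maxx = x
        if y < miny:
            miny = y
        if y > maxy:
            maxy = y
        if maxx - minx + 1 > cutoff or maxy - miny + 1 > cutoff:
            return 1, ncells, branched
        # register candidate moves bonding to the tile just placed
        for d in range(4):
            c = colors[t, (d - o) % 4]
            p = partner[c]
            if p < 0:
                continue
            nx = x + _DX[d]
            ny = y + _DY[d]
            nsi = nx * G + ny
            if occ_stamp[nsi] == stamp:
                continue
            dd = (d + 2) % 4
            kc = match_cnt[p, dd]
            for k in range(kc):
                tt = match_list[p, dd, k, 0]
                oo = match_list[p, dd, k, 1]
                key = (nsi * n_tiles + tt) * 4 + oo
                if seen[key] != stamp:
                    seen[key] = stamp
                    moves[nm, 0] = nsi
                    moves[nm, 1] = tt
                    moves[nm, 2] = oo
                    nm += 1
        # drop moves whose target site has been filled since registration
        w = 0
        for i in range(nm):
            if occ_stamp[moves[i, 0]] != stamp:
                moves[w, 0] = moves[i, 0]
                moves[w, 1] = moves[i, 1]
                moves[w, 2] = moves[i, 2]
                w += 1
        nm = w
        if nm == 0:
            return 0, ncells, branched
        if nm > 1:
            branched = True
        j = np.random.randint(nm)
        si = moves[j, 0]
        t = moves[j, 1]
        o = moves[j, 2]
        x = si // G
        y = si % G


@njit(cache=True)
def _canonical_key(cells, ncells):
    """Free-polyomino canonical form of the first ``ncells`` placed cells.

    Minimum over the 8 square-dihedral transforms of the sorted, translation-
    normalized ``x * STRIDE + y`` encoding.
    """
    tmp = np.empty(ncells, dtype=np.int64)
    best = np.empty(ncells, dtype=np.int64)
    have_best = False
    for tr in range(8):
        minx = np.int64(1 << 40)
        miny = np.int64(1 << 40)
        for i in range(ncells):
            xx = cells[i, 0]
            yy = cells[i, 1]
            if tr == 0:
                tx, ty = xx, yy
            elif tr == 1:
                tx, ty = yy, -xx
            elif tr == 2:
                tx, ty = -xx, -yy
            elif tr == 3:
                tx, ty = -yy, xx
            elif tr == 4:
                tx, ty = -xx, yy
            elif tr == 5:
                tx, ty = xx, -yy
            elif tr == 6:
                tx, ty = yy, xx
            else:
                tx, ty = -yy, -xx
            if tx < minx:
                minx = tx
            if ty < miny:
                miny = ty
            tmp[i] = tx * (1 << 20) + ty
        shift = minx * (1 << 20) + miny
        for i in range(ncells):
            v = tmp[i] - shift
            tmp[i] = (v // (1 << 20)) * STRIDE + (v % (1 << 20))
        tmp.sort()
        if not have_best:
            for i in range(ncells):
                best[i] = tmp[i]
            have_best = True
        else:
            for i in range(ncells):
                if tmp[i] < best[i]:
                    for j in range(ncells):
                        best[j] = tmp[j]
                    break
                elif tmp[i] > best[i]:
                    break
    return best


@njit(cache=True)
def _phenotype_kernel(colors, partner, match_cnt, match_list, cutoff, G,
                      repeats, seed, occ_stamp, occ_tile, occ_orient, seen,
                      moves, cells, stamp_holder, seed_tile):
    """Repeat assembly to determinize: returns (status, key) with status 0 for
    a reproducible bounded shape and 1 for UND (unbounded or nondeterministic).

    Each repeat is seeded from an independent substream.  A run whose move set
    never offered a choice is provably deterministic, so the remaining repeats
    are skipped (unless the seed tile itself is drawn at random).
    """
    _build_match(colors, partner.shape[0], match_cnt, match_list)
    empty = np.empty(0, dtype=np.int64)
    np.random.seed(seed % 2147483647)
    stamp_holder[0] += 1
    st, nc, br = _assemble_trial(colors, partner, match_cnt, match_list,
                                 cutoff, G, occ_stamp, occ_tile, occ_orient,
                                 seen, moves, cells, stamp_holder[0],
                                 seed_tile)
    if st == 1:
        return 1, empty
    key0 = _canonical_key(cells, nc)
    if seed_tile < 0 and colors.shape[0] > 1:
        br = True
    if not br:
        return 0, key0
    for r in range(1, repeats):
        np.random.seed((seed + r * 1013904223) % 2147483647)
        stamp_holder[0] += 1
        st, nc2, br2 = _assemble_trial(colors, partner, match_cnt, match_list,
                                       cutoff, G, occ_stamp, occ_tile,
                                       occ_orient, seen, moves, cells,
                                       stamp_holder[0], seed_tile)
        if st == 1 or nc2 != nc:
            return 1, empty
        key = _canonical_key(cells, nc2)
        for i in range(nc):
            if key[i] != key0[i]:
                return 1, empty
    return 0, key0


@njit(cache=True)
def _sample_chunk(colors_arr, partner, cutoff, G, repeats, seeds,
                  match_cnt, match_list, occ_stamp, occ_tile, occ_orient,
                  seen, moves, cells, stamp_holder, sizes_out, keys_out,
                  offs_out, seed_tile):
    """Phenotype a chunk of genotypes; sizes_out[i] = -1 marks UND."""
    m = colors_arr.shape[0]
    pos = 0
    offs_out[0] = 0
    for i in range(m):
        st, key = _phenotype_kernel(colors_arr[i], partner, match_cnt,
                                    match_list, cutoff, G, repeats, seeds[i],
                                    occ_stamp, occ_tile, occ_orient, seen,
                                    moves, cells, stamp_holder, seed_tile)
        if st == 1:
            sizes_out[i] = -1
        else:
            nc = key.shape[0]
            sizes_out[i] = nc
            for j in range(nc):
                keys_out[pos + j] = key[j]
            pos += nc
        offs_out[i + 1] = pos
    return pos


@njit(cache=True)
def _count_fixed(n):
    """Redelmeier counting of fixed polyominoes of every size up to ``n``.

    Translation classes only (no rotation/reflection quotient); counts[k] is
    the number of fixed k-ominoes.  Iterative depth-first traversal of the
    standard untried-cell recursion with per-level extension buffers.
    """
    W = 2 * n + 1
    H = max(n, 1)
    origin = n  # cell (x=n, y=0); cells with smaller index are forbidden
    occupied = np.zeros(W * H, dtype=np.uint8)
    visited = np.zeros(W * H, dtype=np.uint8)
    counts = np.zeros(n + 1, dtype=np.int64)
    SEG = 4 * n + 16
    buf = np.zeros((n + 2) * SEG, dtype=np.int64)
    undo = np.zeros((n + 2) * SEG, dtype=np.int64)
    lv_top = np.zeros(n + 2, dtype=np.int64)
    lv_cell = np.zeros(n + 2, dtype=np.int64)
    lv_ulo = np.zeros(n + 2, dtype=np.int64)
    buf[0] = origin
    visited[origin] = 1
    lv_top[0] = 1
    upos = 0
    d = 0
    while True:
        if lv_top[d] > 0 and d < n:
            t = lv_top[d] - 1
            c = buf[d * SEG + t]
            lv_top[d] = t
            counts[d + 1] += 1
            if d + 1 < n:
                occupied[c] = 1
                cb = (d + 1) * SEG
                for i in range(t):
                    buf[cb + i] = buf[d * SEG + i]
                m = t
                ulo = upos
                cy = c // W
                cx = c % W
                for k in range(4):
                    if k == 0:
                        nx, ny = cx + 1, cy
                    elif k == 1:
                        nx, ny = cx - 1, cy
                    elif k == 2:
                        nx, ny = cx, cy + 1
                    else:
                        nx, ny = cx, cy - 1
                    if nx < 0 or nx >= W or ny < 0 or ny >= H:
                        continue
                    nb = ny * W + nx
                    if nb < origin:
                        continue
                    if occupied[nb] == 1 or visited[nb] == 1:
                        continue
                    visited[nb] = 1
                    undo[upos] = nb
                    upos += 1
                    buf[cb + m] = nb
                    m += 1
                d += 1
                lv_cell[d] = c
                lv_ulo[d] = ulo
                lv_top[d] = m
        else:
            if d == 0:
                break
            for i in range(lv_ulo[d], upos):
                visited[undo[i]] = 0
            upos = lv_ulo[d]
            occupied[lv_cell[d]] = 0
            d -= 1
    return counts


class Workspace:
    """Reusable scratch arrays for the assembly kernels of one GP map."""

    def __init__(self, n_tiles: int, bits_per_color: int, cutoff: int = 16):
        if cutoff < 1 or 2 * cutoff + 3 >= STRIDE:
            raise ValueError(f"cutoff must be in [1, {(STRIDE - 4) // 2}]")
        self.n_tiles = int(n_tiles)
        self.bits_per_color = int(bits_per_color)
        self.cutoff = int(cutoff)
        self.G = 2 * self.cutoff + 3
        n_colors = 1 << self.bits_per_color
        G2 = self.G * self.G
        self.partner = make_partner_table(self.bits_per_color)
        self.match_cnt = np.zeros((n_colors, 4), dtype=np.int64)
        self.match_list = np.zeros((n_colors, 4, self.n_tiles * 4, 2),
                                   dtype=np.int64)
        self.occ_stamp = np.zeros(G2, dtype=np.int64)
        self.occ_tile = np.zeros(G2, dtype=np.int64)
        self.occ_orient = np.zeros(G2, dtype=np.int64)
        self.seen = np.zeros(G2 * self.n_tiles * 4, dtype=np.int64)
        self.moves = np.zeros((G2 * self.n_tiles * 4, 3), dtype=np.int64)
        self.cells = np.zeros((G2, 4), dtype=np.int64)
        self.stamp = np.zeros(1, dtype=np.int64)

    def phenotype_key(self, colors: np.ndarray, seed: int,
                      repeats: int = 20, seed_tile: int = 0) -> bytes | None:
        """Canonical shape key for one tile set, or None for UND."""
        st, key = _phenotype_kernel(colors, self.partner, self.match_cnt,
                                    self.match_list, self.cutoff, self.G,
                                    repeats, seed, self.occ_stamp,
                                    self.occ_tile, self.occ_orient, self.seen,
                                    self.moves, self.cells, self.stamp,
                                    seed_tile)
        if st == 1:
            return None
        return key.tobytes()

    def assemble_once(self, colors: np.ndarray, seed: int,
                      seed_tile: int = 0):
        """Single assembly trial; returns (status, placements) where
        placements is an (ncells, 4) array of (x, y, tile, orientation)."""
        _build_match(colors, self.partner.shape[0], self.match_cnt,
                     self.match_list)
        np.random.seed(seed % 2147483647)
        self.stamp[0] += 1
        st, nc, _ = _assemble_trial(colors, self.partner, self.match_cnt,
                                    self.match_list, self.cutoff, self.G,
                                    self.occ_stamp, self.occ_tile,
                                    self.occ_orient, self.seen, self.moves,
                                    self.cells, self.stamp[0], seed_tile)
        return st, self.cells[:nc].copy()

    def sample_keys(self, colors_arr: np.ndarray, seeds: np.ndarray,
                    repeats: int = 20, seed_tile: int = 0):
        """Phenotype keys for a chunk of genotypes.

        Returns a list with one entry per genotype: the canonical key bytes,
        or None for UND.
        """
        m = colors_arr.shape[0]
        sizes = np.zeros(m, dtype=np.int64)
        keys = np.zeros(m * self.G * self.G, dtype=np.int64)
        offs = np.zeros(m + 1, dtype=np.int64)
        _sample_chunk(colors_arr, self.partner, self.cutoff, self.G, repeats,
                      seeds, self.match_cnt, self.match_list, self.occ_stamp,
                      self.occ_tile, self.occ_orient, self.seen, self.moves,
                      self.cells, self.stamp, sizes, keys, offs, seed_tile)
        out = []
        for i in range(m):
            if sizes[i] < 0:
                out.append(None)
            else:
                out.append(keys[offs[i]:offs[i + 1]].tobytes())
        return out


def key_to_cells(key: bytes) -> tuple:
    """Decode a canonical key back into a sorted tuple of (x, y) cells."""
    arr = np.frombuffer(key, dtype=np.int64)
    return tuple((int(v) // STRIDE, int(v) % STRIDE) for v in arr)


def cells_to_key(cells) -> bytes:
    """Encode translation-normalized cells (already canonical) as key bytes."""
    arr = np.array(sorted(int(x) * STRIDE + int(y) for x, y in cells),
                   dtype=np.int64)
    return arr.tobytes()
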