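"""The polyomino self-assembly genotype-phenotype map.

A genotype is a binary string of length L = 4*n*b encoding, for each of n
square tile types, four interface colors of b bits each (edge order N, E, S,
W).  Colors bond irreversibly in the unique pairs (1,2), (3,4), ...; color 0
and the maximal color 2**b - 1 are neutral.  Assembly seeds a single copy of
the first-encoded tile on an empty grid and repeatedly plays a uniformly
random *move* — an (empty site, tile type, orientation) triple that would
form at least one bond to the structure — until no move exists (the
phenotype, a polyomino shape) or the bounding box outgrows a cutoff
(unbounded).  Because move choice is stochastic, assembly is repeated
(default 20 times); genotypes whose repeats disagree, or that grow past the
cutoff, map to the special UND phenotype (unbounded or nondeterministic).

The map with up to n tiles and 4n interface colors is written S(n, 4n); the
headline space in this package is S(16, 64), i.e. 16 tiles with 6-bit
colors, L = 384.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._kernels import Workspace, key_to_cells, make_partner_table
from .shapes import Shape


class InvalidGenotypeError(ValueError):
    """Genome string inconsistent with the declared map dimensions."""


class _UndType:
    """Singleton phenotype for unbounded / nondeterministic genotypes."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "UND"

    def __bool__(self):
        return False


#: the UND phenotype marker
UND = _UndType()

#: marker returned by a single unbounded assembly trial
UNBOUNDED = "UNBOUNDED"


@dataclass(frozen=True)
class Tile:
    """One square tile with interface colors in edge order (N, E, S, W)."""

    edge_colors: tuple

    def __post_init__(self):
        if len(self.edge_colors) != 4:
            raise ValueError("a tile has exactly 4 edge colors")

    def rotated(self, quarter_turns: int) -> "Tile":
        """Clockwise rotation: a cyclic shift of the color quadruple."""
        k = quarter_turns % 4
        ec = self.edge_colors
        return Tile(tuple(ec[(i - k) % 4] for i in range(4)))


@dataclass(frozen=True)
class Genotype:
    """A binary genome for an S(n, 4n)-style map."""

    bits: str
    n_tiles: int
    bits_per_color: int

    def __post_init__(self):
        L = 4 * self.n_tiles * self.bits_per_color
        if len(self.bits) != L or set(self.bits) - {"0", "1"}:
            raise InvalidGenotypeError(
                f"genome must be a binary string of length 4*n*b = {L}, "
                f"got length {len(self.bits)}")

    @property
    def length(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class AssemblyOutcome:
    """Determinized assembly result: a Shape, or UND with the reason."""

    result: object  # Shape or UND
    trials: int
    unbounded: bool


def decode_genotype(bits: str, n_tiles: int, bits_per_color: int) -> tuple:
    """Decode a genome into its tile set (big-endian color blocks)."""
    g = Genotype(bits, n_tiles, bits_per_color)
    b = bits_per_color
    tiles = []
    for t in range(n_tiles):
        colors = []
        for e in range(4):
            start = (4 * t + e) * b
            colors.append(int(g.bits[start:start + b], 2))
        tiles.append(Tile(tuple(colors)))
    return tuple(tiles)


def colors_interact(c1: int, c2: int, bits_per_color: int) -> bool:
    """Whether two interface colors bond: {c1, c2} = {2k-1, 2k} for some k,
    with 0 and 2**b - 1 neutral."""
    n_colors = 1 << bits_per_color
    if not (0 <= c1 < n_colors and 0 <= c2 < n_colors):
        raise ValueError(f"colors must lie in [0, {n_colors - 1}]")
    partner = make_partner_table(bits_per_color)
    return bool(partner[c1] == c2)


def _colors_array(tiles: Iterable[Tile]) -> np.ndarray:
    return np.array([t.edge_colors for t in tiles], dtype=np.int64)


def genotype_seed(colors: np.ndarray, master_seed: int = 0) -> int:
    """Deterministic per-genotype RNG seed (CRC of the tile colors XOR the
    master seed), so a genotype's phenotype call is reproducible and
    independent of evaluation order."""
    return (zlib.crc32(colors.tobytes()) ^ (master_seed & 0x7FFFFFFF)) \
        & 0x7FFFFFFF


class PolyominoGPMap:
    """The S(n_tiles, 4*n_tiles) polyomino GP map with its assembly engine.

    Parameters
    ----------
    n_tiles, bits_per_color:
        Map dimensions; genome length is 4 * n_tiles * bits_per_color.
    cutoff:
        Structures whose bounding box exceeds cutoff x cutoff are unbounded.
    repeats:
        Assembly repetitions used to check determinism.
    seed_any_tile:
        If True, each trial seeds assembly from a uniformly random tile type
        instead of the first-encoded tile (an alternative protocol; off by
        default).
    """

    def __init__(self, n_tiles: int = 16, bits_per_color: int = 6,
                 cutoff: int = 16, repeats: int = 20,
                 seed_any_tile: bool = False, master_seed: int = 0):
        self.n_tiles = n_tiles
        self.bits_per_color = bits_per_color
        self.cutoff = cutoff
        self.repeats = repeats
        self.seed_any_tile = seed_any_tile
        self.master_seed = master_seed
        self._seed_tile = -1 if seed_any_tile else 0
        self._ws = Workspace(n_tiles, bits_per_color, cutoff)

    # -- genome handling ---------------------------------------------------

    @property
    def genome_length(self) -> int:
        return 4 * self.n_tiles * self.bits_per_color

    def decode(self, bits: str) -> tuple:
        return decode_genotype(bits, self.n_tiles, self.bits_per_color)

    def colors_of(self, genome) -> np.ndarray:
        """Accept a bit string, Genotype, tile sequence or (n, 4) array and
        return the internal (n_tiles, 4) color array."""
        if isinstance(genome, Genotype):
            genome = genome.bits
        if isinstance(genome, str):
            return _colors_array(self.decode(genome))
        if isinstance(genome, np.ndarray):
            arr = np.ascontiguousarray(genome, dtype=np.int64)
            if arr.shape != (self.n_tiles, 4):
                raise InvalidGenotypeError(
                    f"color array must have shape ({self.n_tiles}, 4)")
            return arr
        if isinstance(genome, Sequence) and genome and \
                isinstance(genome[0], Tile):
            return _colors_array(genome)
        raise TypeError(f"cannot interpret genome of type {type(genome)!r}")

    def bits_to_colors(self, bits_arr: np.ndarray) -> np.ndarray:
        """Vectorized decode of a (L,) or (m, L) 0/1 array into color
        arrays of shape (n_tiles, 4) or (m, n_tiles, 4)."""
        b = self.bits_per_color
        weights = 1 << np.arange(b - 1, -1, -1, dtype=np.int64)
        arr = np.asarray(bits_arr, dtype=np.int64)
        squeeze = arr.ndim == 1
        arr = np.atleast_2d(arr)
        m = arr.shape[0]
        cols = arr.reshape(m, self.n_tiles, 4, b) @ weights
        return cols[0] if squeeze else cols

    # -- assembly ----------------------------------------------------------

    def _seed_for(self, colors: np.ndarray, seed=None) -> int:
        if seed is None:
            return genotype_seed(colors, self.master_seed)
        return int(seed) & 0x7FFFFFFF

    def assemble_once(self, genome, seed=None):
        """One stochastic assembly trial: a Shape (non-canonical cells, seed
        tile at the origin) or the UNBOUNDED marker."""
        colors = self.colors_of(genome)
        st, placements = self._ws.assemble_once(
            colors, self._seed_for(colors, seed), self._seed_tile)
        if st == 1:
            return UNBOUNDED
        center = self._ws.G // 2
        cells = tuple(sorted((int(x) - center, int(y) - center)
                             for x, y, _, _ in placements))
        return Shape(cells, canonical=False)

    def assemble_placements(self, genome, seed=None) -> np.ndarray | None:
        """One trial's full placement record (x, y, tile, orientation) per
        cell, or None if unbounded; used by the interface-complexity
        estimator."""
        colors = self.colors_of(genome)
        st, placements = self._ws.assemble_once(
            colors, self._seed_for(colors, seed), self._seed_tile)
        return None if st == 1 else placements

    def phenotype_key(self, genome, seed=None) -> bytes | None:
        """Canonical phenotype key bytes (fast path), or None for UND."""
        colors = self.colors_of(genome)
        return self._ws.phenotype_key(colors, self._seed_for(colors, seed),
                                      self.repeats, self._seed_tile)

    def phenotype(self, genome, seed=None):
        """Determinized phenotype: canonical Shape or UND."""
        key = self.phenotype_key(genome, seed)
        if key is None:
            return UND
        return Shape(key_to_cells(key))

    def assembly_outcome(self, genome, seed=None) -> AssemblyOutcome:
        key = self.phenotype_key(genome, seed)
        if key is None:
            # distinguish unbounded from nondeterministic via one extra trial
            unbounded = self.assemble_once(genome, seed) is UNBOUNDED
            return AssemblyOutcome(UND, self.repeats, unbounded)
        return AssemblyOutcome(Shape(key_to_cells(key)), self.repeats, False)

    def phenotype_keys_batch(self, colors_arr: np.ndarray,
                             seeds=None) -> list:
        """Phenotype keys for an (m, n_tiles, 4) batch; None marks UND."""
        colors_arr = np.ascontiguousarray(colors_arr, dtype=np.int64)
        if seeds is None:
            seeds = np.array([genotype_seed(colors_arr[i], self.master_seed)
                              for i in range(colors_arr.shape[0])],
                             dtype=np.int64)
        return self._ws.sample_keys(colors_arr, seeds, self.repeats,
                                    self._seed_tile)

    def random_genotypes(self, m: int, rng: np.random.Generator) -> np.ndarray:
        """m genotypes uniform over all 2**L bit strings, as color arrays
        (each color is then independently uniform on [0, 2**b - 1])."""
        return rng.integers(0, 1 << self.bits_per_color,
                            (m, self.n_tiles, 4), dtype=np.int64)


def assemble_once(tiles, seed: int = 0, grid_cutoff: int = 16):
    """Module-level convenience wrapper around one assembly trial."""
    tiles = tuple(tiles)
    bits = max(2, int(max(c for t in tiles for c in t.edge_colors)).bit_length())
    gp = PolyominoGPMap(len(tiles), bits, cutoff=grid_cutoff)
    return gp.assemble_once(tiles, seed=seed)


def phenotype(genotype: Genotype, repeats: int = 20, seed: int = 0):
    """Module-level determinized phenotype of a Genotype."""
    gp = PolyominoGPMap(genotype.n_tiles, genotype.bits_per_color,
                        repeats=repeats)
    return gp.phenotype(genotype, seed=seed)
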