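"""Shared fixtures and independent test oracles.

The oracles here re-derive model behavior by brute force, independently of
the package's kernels: an exhaustive move-tree assembler that enumerates
every possible assembly order of a tile set, and a classic two-pointer
implementation of the LZ76 word count.
"""

from __future__ import annotations

import numpy as np
import pytest

from simbias.polyomino import PolyominoGPMap
from simbias.shapes import canonical_form


@pytest.fixture(scope="session")
def gp_small():
    """The S(2, 8) map: 2 tiles, 3-bit colors."""
    return PolyominoGPMap(2, 3)


@pytest.fixture(scope="session")
def gp_headline():
    """The S(16, 64) map: 16 tiles, 6-bit colors."""
    return PolyominoGPMap(16, 6)


@pytest.fixture(scope="session")
def one_tile_b2_outcomes():
    """Exhaustive move-tree outcomes for every 1-tile, b=2 tile set
    (cutoff 4); None where the oracle state budget is exceeded."""
    import itertools

    table = {}
    for colors in itertools.product(range(4), repeat=4):
        try:
            table[colors] = oracle_outcomes(np.array([colors]), bits=2,
                                            cutoff=4, max_states=200_000)
        except RuntimeError:
            table[colors] = None
    return table


def oracle_partner(c: int, bits: int) -> int:
    """Bonding partner by the pairing rule, -1 if neutral."""
    if c == 0 or c == (1 << bits) - 1:
        return -1
    return c + 1 if c % 2 == 1 else c - 1


def oracle_outcomes(colors, bits: int, cutoff: int = 6,
                    max_states: int = 500_000):
    """Exhaustive move-tree oracle: the set of terminal canonical shapes
    reachable by ANY order of assembly moves, plus "UNBOUNDED" if any
    branch outgrows the cutoff box.

    Breadth-unbounded depth-first walk over assembly states (placements are
    (x, y, tile, orientation) maps); independent of the package kernels.
    """
    colors = np.asarray(colors)
    n_tiles = colors.shape[0]

    def facing(t, o, d):
        return int(colors[t][(d - o) % 4])

    deltas = {0: (0, 1), 1: (1, 0), 2: (0, -1), 3: (-1, 0)}

    def moves_of(placed):
        found = set()
        for (x, y), (t, o) in placed.items():
            for d, (dx, dy) in deltas.items():
                site = (x + dx, y + dy)
                if site in placed:
                    continue
                p = oracle_partner(facing(t, o, d), bits)
                if p < 0:
                    continue
                dd = (d + 2) % 4
                for tt in range(n_tiles):
                    for oo in range(4):
                        if facing(tt, oo, dd) == p:
                            found.add((site, tt, oo))
        return found

    start = ((0, 0, 0, 0),)
    seen = {start}
    stack = [start]
    outcomes = set()
    while stack:
        if len(seen) > max_states:
            raise RuntimeError("oracle state budget exceeded")
        state = stack.pop()
        placed = {(x, y): (t, o) for x, y, t, o in state}
        xs = [x for x, _ in placed]
        ys = [y for _, y in placed]
        if max(xs) - min(xs) + 1 > cutoff or max(ys) - min(ys) + 1 > cutoff:
            outcomes.add("UNBOUNDED")
            continue
        mv = moves_of(placed)
        if not mv:
            outcomes.add(canonical_form(placed.keys()))
            continue
        for (site, tt, oo) in mv:
            child = tuple(sorted(state + ((site[0], site[1], tt, oo),)))
            if child not in seen:
                seen.add(child)
                stack.append(child)
    return outcomes


def oracle_lz76(s: str) -> int:
    """Independent LZ76 word count via explicit copy extension.

    Each word is the longest run copyable character-by-character from a
    source starting strictly before the word (self-overlap allowed), plus
    one fresh symbol; the final, possibly incomplete word counts too.
    """
    n = len(s)
    if n == 0:
        raise ValueError("empty string")
    words = 0
    i = 0
    while i < n:
        longest = 0
        for p in range(i):
            ll = 0
            while i + ll < n and s[p + ll] == s[i + ll]:
                ll += 1
            longest = max(longest, ll)
        words += 1
        i += min(longest + 1, n - i) if n - i > 0 else 1
    return words
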