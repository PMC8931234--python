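"""Descriptional complexity estimators K~(p) for phenotypes.

True Kolmogorov complexity is uncomputable; these are the two computable
proxies used throughout the package:

* :func:`lz_complexity` — a Lempel-Ziv (1976) estimator for binary strings:
  the number of words in the exhaustive production history, symmetrized over
  the string and its reversal and scaled by log2 of the length, with a
  special case assigning log2(n) to the two constant strings.
* :func:`minimal_interface_complexity` — for polyomino phenotypes, the
  number of interface colors that remain essential after redundant genome
  information is removed: sampled genotypes mapping to the phenotype are
  greedily neutralized (colors set to 0 wherever the phenotype survives) and
  the surviving bond-participating colors are counted, taking the minimum
  over samples.  This mirrors the interface-type count used for protein
  complexes: each surface of an asymmetric or heterotypic interface counts
  separately, so one bonded color pair contributes 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import make_partner_table


@dataclass(frozen=True)
class ComplexityValue:
    """A K~(p) estimate: bits for the LZ measure, an integer count for
    interface-based measures."""

    value: float
    method: str

    def __float__(self):
        return float(self.value)


def _check_binary(s: str) -> str:
    if not s:
        raise ValueError("complexity of an empty string is undefined")
    if set(s) - {"0", "1"}:
        raise ValueError("string must be over the alphabet {0, 1}")
    return s


def lz76_words(s: str) -> int:
    """Number of words in the LZ76 exhaustive production history of ``s``.

    Each word is the shortest extension of the parsed prefix that cannot be
    copied from anywhere earlier in the string; the terminal, possibly
    incomplete word counts as a word.
    """
    _check_binary(s)
    n = len(s)
    words = 1
    i = 1
    while i < n:
        # longest reproducible extension starting at i: the word ends one
        # past the longest substring s[i:j] that occurs starting before i
        j = i
        while j < n and s[i:j + 1] in s[:j]:
            j += 1
        words += 1
        i = j + 1
    return words


def lz_complexity(s: str) -> ComplexityValue:
    """LZ76-based complexity estimate in bits.

    Constant strings get log2(n); otherwise log2(n) times the mean of the
    word counts of the string and of its reversal (the measure is thereby
    reversal-symmetric).
    """
    _check_binary(s)
    n = len(s)
    if s.count(s[0]) == n:
        return ComplexityValue(float(np.log2(n)), "lz")
    mean_words = (lz76_words(s) + lz76_words(s[::-1])) / 2.0
    return ComplexityValue(float(np.log2(n)) * mean_words, "lz")


def active_interface_colors(gp_map, colors: np.ndarray, seed=None) -> set:
    """Distinct non-neutral colors participating in at least one realized
    bond in one (deterministically seeded) assembly of the tile set."""
    placements = gp_map.assemble_placements(colors, seed=seed)
    if placements is None:
        raise ValueError("tile set assembles unboundedly")
    partner = make_partner_table(gp_map.bits_per_color)
    occupied = {(int(x), int(y)): (int(t), int(o))
                for x, y, t, o in placements}
    active = set()
    deltas = ((0, 1, 0), (1, 0, 1))  # (dx, dy, direction code N/E)
    for (x, y), (t, o) in occupied.items():
        for dx, dy, d in deltas:
            nb = occupied.get((x + dx, y + dy))
            if nb is None:
                continue
            t2, o2 = nb
            c1 = int(colors[t, (d - o) % 4])
            c2 = int(colors[t2, ((d + 2) % 4 - o2) % 4])
            if partner[c1] == c2:
                active.add(c1)
                active.add(c2)
    return active


def minimal_interface_complexity(phenotype_key: bytes, genotype_samples,
                                 gp_map, budget: int = 100,
                                 seed=None) -> ComplexityValue:
    """Minimal number of interface types over sampled genomes encoding the
    phenotype.

    For each of up to ``budget`` genotypes (given as (n_tiles, 4) color
    arrays, each of which must map to ``phenotype_key``), interface loci are
    scanned in ascending order and set to the neutral color 0 whenever the
    phenotype is unchanged, repeating to a fixed point; the distinct colors
    still realizing bonds in the assembled structure are then counted.  The
    estimate is the minimum over genotypes: it can only decrease with more
    samples.
    """
    samples = list(genotype_samples)[:budget]
    if not samples:
        raise ValueError("at least one generating genotype is required")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    best = None
    for colors in samples:
        cols = np.ascontiguousarray(colors, dtype=np.int64).copy()
        if gp_map.phenotype_key(cols, seed=seed) != phenotype_key:
            raise ValueError("supplied genotype does not map to the target "
                             "phenotype")
        changed = True
        while changed:
            changed = False
            for t in range(gp_map.n_tiles):
                for e in range(4):
                    if cols[t, e] == 0:
                        continue
                    old = cols[t, e]
                    cols[t, e] = 0
                    if gp_map.phenotype_key(cols, seed=seed) == phenotype_key:
                        changed = True
                    else:
                        cols[t, e] = old
        count = len(active_interface_colors(gp_map, cols, seed=seed))
        if best is None or count < best:
            best = count
        if best == 0:
            break
    return ComplexityValue(float(best), "interfaces")
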