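"""Canonicalization, symmetry classification and polyomino enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from simbias.shapes import (BudgetError, DisconnectedShapeError,
                            canonical_form, count_symmetry_classes,
                            enumerate_free, enumerate_invariant, fixed_counts,
                            free_shapes, symmetry_class, _free_shape_set,
                            _invariant_class_count)

# free polyomino counts, derived in-session by brute-force growth
# enumeration with canonical deduplication (and cross-checked below)
FREE_COUNTS = [1, 1, 2, 5, 12, 35, 108, 369]

# how enumerate_invariant's "stabilizer contains G" relates to exact labels
SUPERGROUPS = {
    "C4": {"C4", "D4"},
    "D4": {"D4"},
    "C2": {"C2", "C4", "D2", "D4"},
    "D2": {"D2", "D4"},
    "D1": {"D1", "D2", "D4"},
}


def random_connected_shape(rng, n):
    """Random n-cell connected shape grown by neighbor accretion."""
    cells = {(0, 0)}
    while len(cells) < n:
        x, y = list(cells)[rng.integers(len(cells))]
        nb = [(x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1)]
        cells.add(nb[rng.integers(4)])
    return cells


class TestCanonicalForm:
    def test_monomino(self):
        assert canonical_form({(0, 0)}) == ((0, 0),)

    def test_dominoes_share_canonical_form(self):
        assert canonical_form({(0, 0), (1, 0)}) == \
            canonical_form({(5, 5), (5, 6)})

    def test_l_tromino_rotations_identical(self):
        rotations = [
            {(0, 0), (1, 0), (0, 1)}, {(0, 0), (0, 1), (1, 1)},
            {(1, 0), (1, 1), (0, 1)}, {(0, 0), (1, 0), (1, 1)},
        ]
        forms = {canonical_form(s) for s in rotations}
        assert len(forms) == 1

    def test_disconnected_rejected(self):
        with pytest.raises(DisconnectedShapeError):
            canonical_form({(0, 0), (2, 0)})

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            canonical_form(set())

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_on_random_shapes(self, seed):
        rng = np.random.default_rng(seed)
        shape = random_connected_shape(rng, int(rng.integers(1, 14)))
        once = canonical_form(shape)
        assert canonical_form(once) == once
        # translation-normalized
        assert min(x for x, _ in once) == 0
        assert min(y for _, y in once) == 0


class TestSymmetryClass:
    @pytest.mark.parametrize("cells,label", [
        ({(0, 0)}, "D4"),                                  # monomino
        ({(0, 0), (0, 1)}, "D2"),                          # domino
        ({(0, 0), (1, 0), (1, 1), (2, 1)}, "C2"),          # S-tetromino
        ({(0, 0), (1, 0), (2, 0), (1, 1)}, "D1"),          # T-tetromino
        ({(0, 0), (1, 0), (0, 1), (1, 1)}, "D4"),          # square
        ({(1, 0), (0, 1), (1, 1), (2, 1), (1, 2)}, "D4"),  # plus-pentomino
        ({(0, 0), (1, 0), (2, 0), (0, 1), (0, 2)}, "D1"),  # V-pentomino
        ({(0, 0), (1, 0), (1, 1), (1, 2), (2, 2)}, "C2"),  # Z-pentomino
    ])
    def test_known_shapes(self, cells, label):
        assert symmetry_class(cells).label == label

    def test_d1_flavors(self):
        # T-tetromino mirrors across an axis; staircase corner across the
        # diagonal
        assert symmetry_class({(0, 0), (1, 0), (2, 0), (1, 1)}).flavor == \
            "axis"
        assert symmetry_class({(0, 0), (1, 0), (0, 1)}).flavor == "diagonal"

    def test_invariant_under_transformation(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            shape = random_connected_shape(rng, 9)
            rotated = {(y, -x) for x, y in shape}
            assert symmetry_class(shape) == symmetry_class(rotated)


class TestEnumeration:
    def test_free_counts_match_growth_oracle(self):
        for n, expected in enumerate(FREE_COUNTS, start=1):
            assert len(_free_shape_set(n)) == expected
            assert enumerate_free(n) == expected

    def test_fixed_counts_small(self):
        # 1, 2 and 6 fixed shapes of sizes 1-3 by hand enumeration
        assert fixed_counts(3) == (1, 2, 6)

    def test_iterator_yields_canonical_unique(self):
        shapes = list(free_shapes(5))
        assert len(shapes) == 12
        assert len(set(shapes)) == 12
        assert all(canonical_form(s) == s for s in shapes)

    def test_growth_budget_guard(self):
        with pytest.raises(BudgetError):
            list(free_shapes(30))

    def test_symmetry_class_tally_tetrominoes(self):
        counts = count_symmetry_classes(4)
        direct = {}
        for s in free_shapes(4):
            lbl = symmetry_class(s).label
            direct[lbl] = direct.get(lbl, 0) + 1
        for lbl, c in counts.items():
            assert direct.get(lbl, 0) == c

    @pytest.mark.parametrize("n", [3, 5, 6, 7, 8])
    def test_class_tallies_sum_to_free_count(self, n):
        counts = count_symmetry_classes(n)
        assert sum(counts.values()) == enumerate_free(n)

    def test_large_n_tally_path_matches_direct(self):
        # the symmetric-enumeration + Burnside-subtraction path used beyond
        # the explicit-growth budget must agree with direct classification
        for n in (9, 10):
            direct = {}
            for s in free_shapes(n):
                lbl = symmetry_class(s).label
                direct[lbl] = direct.get(lbl, 0) + 1
            symmetric = (enumerate_invariant(n, "C2")
                         | enumerate_invariant(n, "D1"))
            via_orbits = {}
            for s in symmetric:
                lbl = symmetry_class(s).label
                via_orbits[lbl] = via_orbits.get(lbl, 0) + 1
            via_orbits["C1"] = enumerate_free(n) - len(symmetric)
            for lbl in ("C1", "C2", "C4", "D1", "D2", "D4"):
                assert via_orbits.get(lbl, 0) == direct.get(lbl, 0)


class TestInvariantEnumeration:
    @pytest.mark.parametrize("n", [4, 6, 7, 8])
    @pytest.mark.parametrize("group", sorted(SUPERGROUPS))
    def test_matches_filtered_full_enumeration(self, n, group):
        inv = enumerate_invariant(n, group)
        allowed = SUPERGROUPS[group]
        filtered = {s for s in free_shapes(n)
                    if symmetry_class(s).label in allowed}
        assert inv == filtered

    def test_monomino_is_d4(self):
        assert enumerate_invariant(1, "D4") == {((0, 0),)}

    def test_fourfold_orbit_size_constraint(self):
        # a C4 stabilizer forces n = 0 or 1 (mod 4)
        for n in (2, 3, 6, 7, 10, 11):
            assert enumerate_invariant(n, "C4") == set()
        for n in (4, 5, 8, 9):
            assert enumerate_invariant(n, "C4")

    def test_unsupported_group_rejected(self):
        with pytest.raises(ValueError):
            enumerate_invariant(4, "C3")

    def test_burnside_terms_consistency(self):
        # Burnside reconstruction at n=6: identity term plus the symmetric
        # invariant-class counts must equal 8 * free count
        n = 6
        total = (fixed_counts(n)[n - 1]
                 + 2 * _invariant_class_count(n, "r90")
                 + _invariant_class_count(n, "r180")
                 + 2 * _invariant_class_count(n, "mirror")
                 + 2 * _invariant_class_count(n, "diagonal"))
        assert total == 8 * enumerate_free(n)
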