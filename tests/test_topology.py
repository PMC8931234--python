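"""Interaction-graph topologies: interface counts, permutation symmetry and
the 6-mer morphospace."""

import itertools

import pytest

from simbias.topology import (InteractionGraph, Interface,
                              enumerate_6mer_morphospace, heterodimer,
                              homodimer, interface_type_count, monomer,
                              permutation_symmetry)


def ring(n, types, kind, interface_id=0):
    edges = tuple(Interface(i, (i + 1) % n, interface_id, kind)
                  for i in range(n))
    return InteractionGraph(tuple(types), edges)


class TestValidation:
    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            InteractionGraph((0, 0), (Interface(0, 0, 0, "symmetric"),))

    def test_symmetric_interface_requires_same_types(self):
        with pytest.raises(ValueError):
            InteractionGraph((0, 1), (Interface(0, 1, 0, "symmetric"),))

    def test_hetero_interface_requires_distinct_types(self):
        with pytest.raises(ValueError):
            InteractionGraph((0, 0), (Interface(0, 1, 0, "hetero"),))

    def test_disconnected_rejected(self):
        with pytest.raises(ValueError):
            InteractionGraph((0, 0, 0), (Interface(0, 1, 0, "symmetric"),))


class TestInterfaceTypeCount:
    def test_monomer_zero(self):
        assert interface_type_count(monomer()) == 0

    def test_symmetric_homodimer_one(self):
        assert interface_type_count(homodimer(symmetric=True)) == 1

    def test_heterodimer_two(self):
        assert interface_type_count(heterodimer()) == 2

    def test_asymmetric_ring_two(self):
        # a cyclic homomeric ring bound by one asymmetric interface exposes
        # the two surfaces of that interface, like a heterodimer
        g = ring(6, [0] * 6, "asymmetric")
        assert interface_type_count(g) == 2

    def test_invariant_under_relabeling(self):
        g1 = InteractionGraph((0, 1, 1), (Interface(0, 1, 0, "hetero"),
                                          Interface(1, 2, 1, "symmetric")))
        g2 = InteractionGraph((1, 0, 0), (Interface(0, 1, 5, "hetero"),
                                          Interface(1, 2, 9, "symmetric")))
        assert interface_type_count(g1) == interface_type_count(g2)


class TestPermutationSymmetry:
    def test_distinct_type_path_is_c1(self):
        g = InteractionGraph(tuple(range(6)),
                             tuple(Interface(i, i + 1, i, "hetero")
                                   for i in range(5)))
        count, cat = permutation_symmetry(g)
        assert (count, cat) == (1, "C1")

    def test_asymmetric_homomeric_ring_collapsed_category(self):
        count, cat = permutation_symmetry(ring(6, [0] * 6, "asymmetric"))
        assert count == 6  # rotations only: orientation kills reflections
        assert cat == "C6/D3"

    def test_alternating_type_ring_is_c3(self):
        count, cat = permutation_symmetry(ring(6, [0, 1] * 3, "hetero"))
        assert count == 6  # dihedral on three AB units
        assert cat == "C3"

    def test_prism_collapses_to_c6_d3(self):
        tri1 = [Interface(a, b, 0, "symmetric") for a, b in
                ((0, 1), (1, 2), (2, 0))]
        tri2 = [Interface(a, b, 0, "symmetric") for a, b in
                ((3, 4), (4, 5), (5, 3))]
        rungs = [Interface(i, i + 3, 1, "symmetric") for i in range(3)]
        g = InteractionGraph((0,) * 6, tuple(tri1 + tri2 + rungs))
        count, cat = permutation_symmetry(g)
        assert count == 12
        assert cat == "C6/D3"

    def test_symmetric_dimer_of_trimers_is_c2(self):
        # two ABC heterotrimers joined by one homomeric interface on A
        edges = (Interface(0, 1, 0, "hetero"), Interface(1, 2, 1, "hetero"),
                 Interface(3, 4, 0, "hetero"), Interface(4, 5, 1, "hetero"),
                 Interface(0, 3, 2, "symmetric"))
        g = InteractionGraph((0, 1, 2, 0, 1, 2), edges)
        count, cat = permutation_symmetry(g)
        assert (count, cat) == (2, "C2")

    def test_star_warns_and_falls_back(self):
        star = InteractionGraph((0,) * 6,
                                tuple(Interface(0, i, 0, "symmetric")
                                      for i in range(1, 6)))
        with pytest.warns(UserWarning):
            count, cat = permutation_symmetry(star)
        assert count == 120  # S5 on the leaves
        assert cat == "C1"   # no fixed-point-free automorphism

    def test_automorphism_count_divides_720(self):
        for g in (ring(6, [0] * 6, "symmetric"), heterodimer_hexamer()):
            count, _ = permutation_symmetry(g)
            assert 720 % count == 0


def heterodimer_hexamer():
    """Three AB heterodimers in a ring (A-B hetero, B-A via second type)."""
    edges = []
    for i in range(6):
        kind = "hetero"
        iid = i % 2
        edges.append(Interface(i, (i + 1) % 6, iid, kind))
    return InteractionGraph((0, 1) * 3, tuple(edges))


class TestMorphospace:
    def test_homomeric_trees_include_path_and_star(self):
        graphs = list(enumerate_6mer_morphospace(max_types=1,
                                                 trees_only=True))
        degree_seqs = set()
        for g in graphs:
            deg = [0] * 6
            for e in g.edges:
                deg[e.a] += 1
                deg[e.b] += 1
            degree_seqs.add(tuple(sorted(deg)))
        assert (1, 1, 2, 2, 2, 2) in degree_seqs  # path
        assert (1, 1, 1, 1, 1, 5) in degree_seqs  # star

    def test_all_outputs_connected_valid(self):
        for g in itertools.islice(enumerate_6mer_morphospace(max_types=2,
                                                             trees_only=True),
                                  200):
            assert g.n_nodes == 6  # construction validates connectivity

    def test_no_two_outputs_isomorphic(self):
        graphs = list(enumerate_6mer_morphospace(max_types=1,
                                                 trees_only=True))
        # pairwise isomorphism oracle: try all node permutations
        for i, g1 in enumerate(graphs):
            for g2 in graphs[i + 1:]:
                assert not _isomorphic(g1, g2)

    def test_tree_count_matches_bruteforce_for_symmetric_flags(self):
        # symmetric-flag homomeric trees on 6 nodes = free trees = 6
        graphs = [g for g in enumerate_6mer_morphospace(max_types=1,
                                                        trees_only=True)
                  if all(e.kind == "symmetric" for e in g.edges)]
        assert len(graphs) == 6


def _isomorphic(g1, g2):
    if sorted(g1.node_types) != sorted(g2.node_types) or \
            len(g1.edges) != len(g2.edges):
        return False
    kinds1 = sorted(e.kind for e in g1.edges)
    if kinds1 != sorted(e.kind for e in g2.edges):
        return False

    def edge_set(g, perm, type_map):
        out = set()
        for e in g.edges:
            a, b = perm[e.a], perm[e.b]
            if e.kind == "asymmetric":
                out.add((a, b, e.kind))
            else:
                out.add((min(a, b), max(a, b), e.kind))
        return out

    base = edge_set(g2, list(range(6)), None)
    types2 = g2.node_types
    for perm in itertools.permutations(range(6)):
        if any(g1.node_types[i] != types2[perm[i]] for i in range(6)):
            # allow type relabeling: build the induced map and check
            mapping = {}
            ok = True
            for i in range(6):
                t1, t2 = g1.node_types[i], types2[perm[i]]
                if mapping.setdefault(t1, t2) != t2:
                    ok = False
                    break
            if not ok:
                continue
        if edge_set(g1, list(perm), None) == base:
            return True
    return False
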