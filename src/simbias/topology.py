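"""Protein-complex bonding topologies as typed interaction graphs.

A complex is a connected graph whose nodes are subunit instances carrying a
subunit-type label and whose edges carry an interface-type identity.  An
interface type between two copies of the same subunit type is *homomeric*
and is either symmetric (one self-complementary surface) or asymmetric (two
distinct surfaces); interfaces between different subunit types are
heterotypic and always involve two distinct surfaces.  The complexity
measure K~(p) is the number of distinct binding *surfaces*: a symmetric
homomeric interface contributes 1, an asymmetric or heterotypic interface
contributes 2, and an edgeless monomer scores 0.

Spatial symmetry is approximated by node-permutation symmetry: the
automorphisms of the typed, interface-labeled graph (for 6-mers, all 720
permutations are checked).  The category reported is the largest k in
{6, 3, 2} such that some automorphism moves every node in cycles of length
exactly k; sixfold rings and threefold-dihedral prisms both admit a
single-6-cycle automorphism, so D3 and C6 collapse into one category,
distinct from C3, C2 and C1.  Automorphism groups richer than any planar
ring symmetry (e.g. star graphs) fall back to the largest compatible cyclic
category with a warning.

Curation of real structures (interface-size weighting, pruning of small
interfaces) is assumed to have happened upstream; this module consumes
final topologies.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx

VALID_KINDS = ("symmetric", "asymmetric", "hetero")


@dataclass(frozen=True)
class Interface:
    """One edge: subunit instances a-b bound via interface type
    ``interface_id``.

    For asymmetric homomeric interfaces the order (a, b) is meaningful: a
    presents the first surface and b the second.  For symmetric and
    heterotypic interfaces the order is irrelevant.
    """

    a: int
    b: int
    interface_id: int
    kind: str


@dataclass(frozen=True)
class InteractionGraph:
    """A typed-subunit interaction graph of a protein complex."""

    node_types: tuple
    edges: tuple = field(default_factory=tuple)

    def __post_init__(self):
        n = len(self.node_types)
        kinds: dict = {}
        for e in self.edges:
            if not (0 <= e.a < n and 0 <= e.b < n):
                raise ValueError(f"edge {e} references an unknown node")
            if e.a == e.b:
                raise ValueError("an interface joins two subunit instances; "
                                 "self-loops are not allowed")
            if e.kind not in VALID_KINDS:
                raise ValueError(f"unknown interface kind {e.kind!r}")
            same_type = self.node_types[e.a] == self.node_types[e.b]
            if e.kind == "symmetric" and not same_type:
                raise ValueError("a symmetric interface requires identical "
                                 "subunit types")
            if e.kind == "hetero" and same_type:
                raise ValueError("a heterotypic interface requires distinct "
                                 "subunit types")
            if e.kind in ("symmetric", "asymmetric") and not same_type:
                raise ValueError("homomeric interfaces join same-type "
                                 "subunits")
            prev = kinds.setdefault(e.interface_id, e.kind)
            if prev != e.kind:
                raise ValueError(f"interface type {e.interface_id} used "
                                 f"with two kinds ({prev}, {e.kind})")
        if n > 1:
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from((e.a, e.b) for e in self.edges)
            if not nx.is_connected(g):
                raise ValueError("interaction graph must be connected")

    @property
    def n_nodes(self) -> int:
        return len(self.node_types)

    def interface_kinds(self) -> dict:
        return {e.interface_id: e.kind for e in self.edges}


def monomer(node_type=0) -> InteractionGraph:
    return InteractionGraph((node_type,))


def homodimer(symmetric: bool = True) -> InteractionGraph:
    kind = "symmetric" if symmetric else "asymmetric"
    return InteractionGraph((0, 0), (Interface(0, 1, 0, kind),))


def heterodimer() -> InteractionGraph:
    return InteractionGraph((0, 1), (Interface(0, 1, 0, "hetero"),))


_KIND_SURFACES = {"symmetric": 1, "asymmetric": 2, "hetero": 2}


def interface_type_count(g: InteractionGraph) -> int:
    """Number of distinct binding surfaces of the complex (the K~(p) of
    interaction-graph phenotypes): 1 per symmetric homomeric interface
    type, 2 per asymmetric or heterotypic type, 0 for a monomer."""
    return sum(_KIND_SURFACES[kind] for kind in g.interface_kinds().values())


def _edge_lookup(g: InteractionGraph) -> dict:
    table = {}
    for e in g.edges:
        if e.kind == "asymmetric":
            table[(e.a, e.b)] = (e.interface_id, e.kind, True)
        else:
            table[frozenset((e.a, e.b))] = (e.interface_id, e.kind, False)
    return table


def automorphisms(g: InteractionGraph):
    """All node permutations preserving types, adjacency, interface
    identities and asymmetric-surface orientation."""
    n = g.n_nodes
    if n > 8:
        raise ValueError("automorphism search is limited to <= 8 nodes")
    table = _edge_lookup(g)
    autos = []
    for perm in itertools.permutations(range(n)):
        if any(g.node_types[perm[i]] != g.node_types[i] for i in range(n)):
            continue
        ok = True
        for e in g.edges:
            if e.kind == "asymmetric":
                img = table.get((perm[e.a], perm[e.b]))
            else:
                img = table.get(frozenset((perm[e.a], perm[e.b])))
            if img is None or img[0] != e.interface_id:
                ok = False
                break
        if ok and len(table) == len({
                (perm[e.a], perm[e.b]) if e.kind == "asymmetric"
                else frozenset((perm[e.a], perm[e.b]))
                for e in g.edges}):
            autos.append(perm)
    return autos


def _cycle_lengths(perm) -> list:
    n = len(perm)
    seen = [False] * n
    lens = []
    for i in range(n):
        if seen[i]:
            continue
        ln = 0
        j = i
        while not seen[j]:
            seen[j] = True
            j = perm[j]
            ln += 1
        lens.append(ln)
    return lens


def permutation_symmetry(g: InteractionGraph):
    """(automorphism count, symmetry category) of a 6-subunit complex.

    The category is C6/D3, C3, C2 or C1, assigned from the largest k for
    which a fixed-point-free automorphism with uniform cycle length k
    exists.
    """
    autos = automorphisms(g)
    count = len(autos)
    if g.n_nodes != 6:
        return count, None
    best = 1
    for perm in autos:
        lens = _cycle_lengths(perm)
        if len(set(lens)) == 1 and lens[0] > 1:
            best = max(best, lens[0])
    if count > 12:
        warnings.warn(
            f"automorphism group of order {count} exceeds any planar ring "
            "symmetry; falling back to the largest compatible cyclic "
            "category", stacklevel=2)
    category = {6: "C6/D3", 3: "C3", 2: "C2", 1: "C1"}[best]
    return count, category


# ---------------------------------------------------------------------------
# morphospace enumeration

def _connected_graphs(n: int):
    """Connected simple graphs on n nodes, one representative per
    isomorphism class, as sorted edge tuples."""
    all_edges = list(itertools.combinations(range(n), 2))
    ne = len(all_edges)
    perms = list(itertools.permutations(range(n)))
    # mask permutation tables: position of each edge image
    perm_maps = []
    edge_index = {e: i for i, e in enumerate(all_edges)}
    for perm in perms:
        perm_maps.append([edge_index[tuple(sorted((perm[a], perm[b])))]
                          for a, b in all_edges])
    seen = set()
    reps = []
    for mask in range(1, 1 << ne):
        if mask in seen:
            continue
        edges = [all_edges[i] for i in range(ne) if mask >> i & 1]
        g = nx.Graph(edges)
        if g.number_of_nodes() != n or not nx.is_connected(g):
            continue
        orbit = set()
        for pm in perm_maps:
            m2 = 0
            for i in range(ne):
                if mask >> i & 1:
                    m2 |= 1 << pm[i]
            orbit.add(m2)
        seen |= orbit
        reps.append(tuple(sorted(edges)))
    return reps


def _canonical_typed(n, edges, types, flags, orientations):
    """Canonical form of a typed/flagged graph under node permutation and
    type relabeling; ``flags`` maps homomeric type pairs to symmetric /
    asymmetric, ``orientations`` orders the endpoints of asymmetric edges."""
    best = None
    for perm in itertools.permutations(range(n)):
        relabel: dict = {}
        ptypes = []
        for i in range(n):
            t = types[perm[i]]
            ptypes.append(relabel.setdefault(t, len(relabel)))
        pedges = []
        for a, b in edges:
            ia, ib = perm.index(a), perm.index(b)
            tp = tuple(sorted((types[a], types[b])))
            kind = flags.get(tp, "hetero")
            if kind == "asymmetric":
                a0, b0 = orientations[(a, b)]
                ia0, ib0 = perm.index(a0), perm.index(b0)
                pedges.append((min(ia0, ib0), max(ia0, ib0), kind,
                               ia0 > ib0))
            else:
                pedges.append((min(ia, ib), max(ia, ib), kind, False))
        cand = (tuple(ptypes), tuple(sorted(pedges)))
        if best is None or cand < best:
            best = cand
    return best


def enumerate_6mer_morphospace(max_types: int = 6, n_nodes: int = 6,
                               trees_only: bool = False):
    """The morphospace of hypothetical complexes: all connected typed graphs
    on ``n_nodes`` subunits with up to ``max_types`` subunit types and each
    homomeric interface flagged symmetric or asymmetric.

    Interface identities follow the one-type-per-subunit-type-pair
    convention (multi-interface pairs are excluded, as are multi-edges).
    Yields InteractionGraph objects, one per equivalence class under node
    permutation and type relabeling.  The full space is large; restrict
    ``max_types`` (or pass ``trees_only=True``) for tractable slices.
    """
    if not 1 <= max_types <= n_nodes:
        raise ValueError("max_types must be in [1, n_nodes]")
    base = _connected_graphs(n_nodes)
    if trees_only:
        base = [edges for edges in base if len(edges) == n_nodes - 1]
    seen = set()
    for edges in base:
        for types in itertools.product(range(max_types), repeat=n_nodes):
            # canonical type usage: first occurrences in increasing order
            order: dict = {}
            for t in types:
                order.setdefault(t, len(order))
            if list(order) != sorted(order):
                continue
            homo_pairs = sorted({(types[a], types[b]) for a, b in edges
                                 if types[a] == types[b]})
            hetero_pairs = {tuple(sorted((types[a], types[b])))
                            for a, b in edges if types[a] != types[b]}
            for kinds in itertools.product(("symmetric", "asymmetric"),
                                           repeat=len(homo_pairs)):
                flags = dict(zip(homo_pairs, kinds))
                asym_edges = [(a, b) for a, b in edges
                              if flags.get((types[a], types[b]))
                              == "asymmetric"]
                for orient_bits in itertools.product(
                        (False, True), repeat=len(asym_edges)):
                    orientations = {}
                    for (a, b), flip in zip(asym_edges, orient_bits):
                        orientations[(a, b)] = (b, a) if flip else (a, b)
                    canon = _canonical_typed(n_nodes, edges, types, flags,
                                             orientations)
                    if canon in seen:
                        continue
                    seen.add(canon)
                    iface_ids = {}
                    glist = []
                    for a, b in edges:
                        tp = tuple(sorted((types[a], types[b])))
                        iid = iface_ids.setdefault(tp, len(iface_ids))
                        if tp in flags:
                            kind = flags[tp]
                            if kind == "asymmetric":
                                a0, b0 = orientations[(a, b)]
                                glist.append(Interface(a0, b0, iid, kind))
                            else:
                                glist.append(Interface(a, b, iid, kind))
                        else:
                            glist.append(Interface(a, b, iid, "hetero"))
                    yield InteractionGraph(tuple(types), tuple(glist))
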