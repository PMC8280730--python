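"""Atom mapping, hybrid topologies, dummy partitioning and junctions.

In the single-topology paradigm one set of particles morphs between two end
states A and B; atoms of the larger state that have no counterpart in the
smaller one persist there as *dummy atoms*.  The hybrid topology at an
endpoint therefore contains all atoms of that endpoint's physical molecule
plus the other endpoint's unmapped atoms, renamed ``D_<source name>`` and
bonded through the atom map.  Dummy bonded terms inherit the force-field
parameters they carry at the end state where those atoms are physical.

Junctions -- the attachment sites of dummy groups -- are classified by the
number of *physical* atoms bonded to the physical bridge atom X: one makes a
terminal junction, two a dual junction, three a triple junction (planar or
nonplanar, decided from reference geometry), four or more a "higher"
junction, which is handled through the dual-topology reduction.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .molgraph import (
    AngleTerm,
    Atom,
    BondTerm,
    DihedralTerm,
    ImproperTerm,
    Topology,
    TopologyError,
    UreyBradleyTerm,
    term_label,
)

__all__ = [
    "AtomMap",
    "DummyPartition",
    "Junction",
    "build_hybrid",
    "partition_dummies",
    "classify_junctions",
    "find_atom_map",
]


@dataclass
class AtomMap:
    """Injective pairing of atom ids between end states A and B."""

    pairs: list[tuple[str, str]]

    def __post_init__(self):
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("atom map must be injective on both sides")

    @property
    def a_to_b(self) -> dict[str, str]:
        return dict(self.pairs)

    @property
    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}

    def mapped(self, endpoint: str) -> set[str]:
        return {p[0] if endpoint == "A" else p[1] for p in self.pairs}

    def to_json(self) -> dict:
        return {"pairs": [[f"A:{a}", f"B:{b}"] for a, b in self.pairs]}

    @classmethod
    def from_json(cls, data: dict) -> "AtomMap":
        pairs = []
        for a, b in data["pairs"]:
            pairs.append((a.split(":", 1)[-1], b.split(":", 1)[-1]))
        return cls(pairs)

    def validate(self, top_a: Topology, top_b: Topology) -> None:
        """Mapped atoms must induce isomorphic connectivity on the core."""
        ab = self.a_to_b
        for a in ab:
            if a not in top_a.atoms:
                raise ValueError(f"map references unknown atom {a!r} in state A")
        for b in ab.values():
            if b not in top_b.atoms:
                raise ValueError(f"map references unknown atom {b!r} in state B")
        ga, gb = top_a.graph(), top_b.graph()
        for a1, a2 in itertools.combinations(ab, 2):
            if ga.has_edge(a1, a2) != gb.has_edge(ab[a1], ab[a2]):
                raise ValueError(
                    f"mapped core not isomorphic: bond {a1}-{a2} vs {ab[a1]}-{ab[a2]}"
                )


# --------------------------------------------------------------------------
# hybrid construction
# --------------------------------------------------------------------------


def dummy_name(source_id: str) -> str:
    return source_id if source_id.startswith("D_") else f"D_{source_id}"


def build_hybrid(top_a: Topology, top_b: Topology, amap: AtomMap,
                 endpoint: str) -> Topology:
    """Materialize the hybrid topology at one endpoint.

    At endpoint B the physical molecule is B; the unmapped atoms of A become
    dummies named ``D_<A name>``, carrying A's connectivity (translated
    through the map) and every bonded term of A that involves at least one
    of them, with A's parameters.  Total atom count is identical at both
    endpoints (particle number is conserved along the alchemical path).
    """
    if endpoint not in ("A", "B"):
        raise ValueError("endpoint must be 'A' or 'B'")
    amap.validate(top_a, top_b)
    if endpoint == "A":
        top_a, top_b = top_b, top_a
        amap = AtomMap([(b, a) for a, b in amap.pairs])
    # from here on: physical endpoint is "B" (top_b), dummies come from top_a
    ab = amap.a_to_b

    hyb = top_b.copy()
    trans: dict[str, str] = dict(ab)  # source id -> hybrid id
    for a in top_a.atoms.values():
        if a.id in ab:
            continue
        did = dummy_name(a.id)
        trans[a.id] = did
        hyb.add_atom(Atom(id=did, element=a.element, name=did, coords=None,
                          charge=0.0, is_dummy=True))
    for b1, b2 in top_a.bonds:
        if b1 in ab and b2 in ab:
            continue
        hyb.add_bond(trans[b1], trans[b2])

    def tr(atoms):
        return tuple(trans[a] for a in atoms)

    def has_dummy(atoms):
        return any(a not in ab for a in atoms)

    for t in top_a.bond_terms:
        if has_dummy(t.atoms):
            hyb.bond_terms.append(BondTerm(tr(t.atoms), t.k, t.b0))
    for t in top_a.angle_terms:
        if has_dummy(t.atoms):
            hyb.angle_terms.append(AngleTerm(tr(t.atoms), t.k, t.theta0))
    for t in top_a.urey_bradley_terms:
        # UB membership follows its parent angle: translated if any member of
        # the parent angle (outer atoms or center) is a dummy
        parent = next(
            (a for a in top_a.angle_terms if frozenset(a.outer) == frozenset(t.atoms)),
            None,
        )
        members = parent.atoms if parent else t.atoms
        if has_dummy(members):
            hyb.urey_bradley_terms.append(UreyBradleyTerm(tr(t.atoms), t.k, t.s0))
    for t in top_a.dihedral_terms:
        if has_dummy(t.atoms):
            hyb.dihedral_terms.append(DihedralTerm(tr(t.atoms), t.k, t.n, t.delta))
    for t in top_a.improper_terms:
        if has_dummy(t.atoms):
            hyb.improper_terms.append(ImproperTerm(tr(t.atoms), t.k, t.psi0))

    # dummies enter without coordinates until a placement step (Kabsch
    # transplant from the source state) provides the full set
    hyb.validate(require_connected=True, check_coords=False)
    return hyb


# --------------------------------------------------------------------------
# dummy partition
# --------------------------------------------------------------------------


@dataclass
class DummyPartition:
    """Dummy/physical labeling of one endpoint's hybrid topology."""

    endpoint: str
    dummy_atoms: set[str]
    dummy_groups: list[set[str]]
    physical_bridge_atoms: list[set[str]]   # per group: the X atoms
    dummy_bridge_atoms: list[set[str]]      # per group: dummies bonded to X
    bridge_bonds: list[set[tuple[str, str]]]

    @property
    def n_dummies(self) -> int:
        return len(self.dummy_atoms)

    def group_of(self, dummy_id: str) -> int:
        for n, grp in enumerate(self.dummy_groups):
            if dummy_id in grp:
                return n
        raise KeyError(dummy_id)


def partition_dummies(hybrid: Topology, endpoint: str = "B",
                      dummy_atoms: set[str] | None = None) -> DummyPartition:
    """Partition a hybrid topology into dummy groups with bridge bookkeeping.

    The dummy set defaults to the atoms flagged ``is_dummy`` by
    :func:`build_hybrid`.  Groups are the connected components of the
    dummy-induced subgraph; each group must reach the physical system through
    at least one bridge bond.
    """
    dummies = set(dummy_atoms) if dummy_atoms is not None else hybrid.dummy_atoms()
    g = hybrid.graph()
    sub = g.subgraph(dummies)
    groups = [set(c) for c in nx.connected_components(sub)]
    groups.sort(key=lambda c: sorted(c)[0])
    phys_bridges, dum_bridges, bbonds = [], [], []
    for grp in groups:
        xs, dbs, bonds = set(), set(), set()
        for d in grp:
            for nb in g.neighbors(d):
                if nb not in dummies:
                    xs.add(nb)
                    dbs.add(d)
                    bonds.add(tuple(sorted((d, nb))))
        if not bonds:
            raise TopologyError(
                f"dummy group {sorted(grp)} is detached from the physical system"
            )
        phys_bridges.append(xs)
        dum_bridges.append(dbs)
        bbonds.append(bonds)
    assert sum(len(grp) for grp in groups) == len(dummies)
    return DummyPartition(
        endpoint=endpoint,
        dummy_atoms=dummies,
        dummy_groups=groups,
        physical_bridge_atoms=phys_bridges,
        dummy_bridge_atoms=dum_bridges,
        bridge_bonds=bbonds,
    )


# --------------------------------------------------------------------------
# junction classification
# --------------------------------------------------------------------------

_KINDS = {1: "terminal", 2: "dual", 3: "triple"}


@dataclass
class Junction:
    """One classified dummy attachment site."""

    bridge_atom: str                       # the physical bridge atom X
    kind: str                              # terminal / dual / triple / higher
    physical_neighbors: list[str]
    dummy_groups: list[int]                # indices into partition.dummy_groups
    planar: bool | None = None             # triple/higher only
    is_dual_topology: bool = False


def _planarity(coords: np.ndarray, tol: float) -> bool:
    """True if four points are coplanar within an out-of-plane distance tol."""
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s[-1] <= tol)


def classify_junctions(hybrid: Topology, partition: DummyPartition,
                       reference_coords: np.ndarray | None = None,
                       planar_tol: float = 0.05,
                       planar_override: dict[str, bool] | None = None,
                       dual_topology_bridges: set[str] | None = None,
                       ) -> list[Junction]:
    """One :class:`Junction` per physical bridge atom.

    Planarity of a triple junction is decided geometrically: X and its three
    physical neighbors must be coplanar within ``planar_tol`` (A, out-of-plane
    displacement) on the reference geometry.  ``planar_override`` forces the
    verdict per bridge atom (the distinction is chemical -- sp2 vs sp3 --
    and a user may know better than the reference coordinates).
    """
    g = hybrid.graph()
    overrides = planar_override or {}
    dt_bridges = dual_topology_bridges or set()
    ids = list(hybrid.atoms)
    pos = {a: n for n, a in enumerate(ids)}

    by_x: dict[str, list[int]] = {}
    for gi, xs in enumerate(partition.physical_bridge_atoms):
        for x in xs:
            by_x.setdefault(x, []).append(gi)

    junctions = []
    for x in sorted(by_x):
        phys_nb = sorted(
            nb for nb in g.neighbors(x) if nb not in partition.dummy_atoms
        )
        if not phys_nb:
            raise TopologyError(
                f"bridge atom {x!r} has no physical neighbor (entire molecule is dummy)"
            )
        kind = _KINDS.get(len(phys_nb), "higher")
        planar = None
        if kind in ("triple", "higher"):
            if x in overrides:
                planar = overrides[x]
            elif reference_coords is not None:
                quad = np.asarray(reference_coords)[[pos[x]] + [pos[p] for p in phys_nb[:3]]]
                planar = _planarity(quad, planar_tol)
            else:
                planar = False
        junctions.append(
            Junction(
                bridge_atom=x,
                kind=kind,
                physical_neighbors=phys_nb,
                dummy_groups=sorted(by_x[x]),
                planar=planar,
                is_dual_topology=x in dt_bridges,
            )
        )
    return junctions


# --------------------------------------------------------------------------
# maximum common connected substructure (convenience; fixtures pin maps)
# --------------------------------------------------------------------------


def find_atom_map(top_a: Topology, top_b: Topology,
                  match_elements: bool = True, max_nodes: int = 16) -> AtomMap:
    """Element-matched maximum common *connected* substructure search.

    Exhaustive anchored DFS, adequate for the small molecules this package
    handles.  Tie-break: most mapped heavy atoms, then most mapped hydrogens,
    then lexicographic atom order.  Paper-style maps that change an element
    across the transformation must be supplied explicitly instead.
    """
    ga, gb = top_a.graph(), top_b.graph()
    if len(ga) > max_nodes or len(gb) > max_nodes:
        raise ValueError("molecule too large for the exhaustive MCS search")
    ea = {a.id: a.element for a in top_a.atoms.values()}
    eb = {b.id: b.element for b in top_b.atoms.values()}

    best: dict[str, str] = {}
    best_key: tuple = (-1, -1, ())

    def score(m: dict[str, str]):
        heavy = sum(1 for a in m if ea[a] != "H")
        light = len(m) - heavy
        # deterministic tie-break: earliest pairs in lexicographic order win
        order = tuple((a, m[a]) for a in sorted(m))
        return (heavy, light, tuple(tuple(-ord(c) for c in a + b) for a, b in order))

    def compatible(a, b, m):
        if match_elements and ea[a] != eb[b]:
            return False
        # consistency: every mapped neighbor relation must agree
        for a2, b2 in m.items():
            if ga.has_edge(a, a2) != gb.has_edge(b, b2):
                return False
        return True

    def extend(m: dict[str, str], frontier: list[str]):
        nonlocal best, best_key
        key = score(m)
        if key > best_key:
            best, best_key = dict(m), key
        # candidate A atoms adjacent to the mapped core
        cand_a = sorted(
            {n for a in m for n in ga.neighbors(a)} - set(m)
        )
        if not cand_a:
            return
        a = cand_a[0]
        mapped_b = set(m.values())
        for b in sorted(set(gb) - mapped_b):
            if any(gb.has_edge(b, m[a2]) for a2 in m if ga.has_edge(a, a2)) and \
               compatible(a, b, m):
                m[a] = b
                extend(m, frontier)
                del m[a]
        # also allow skipping atom a entirely (it stays unmapped)
        remaining = {n for x in m for n in ga.neighbors(x)} - set(m) - {a}
        if remaining:
            # recurse over the reduced frontier by temporarily removing a
            ga.remove_node(a)
            try:
                extend(m, frontier)
            finally:
                ga.add_node(a)
                for n in top_a.graph().neighbors(a):
                    if ga.has_node(n):
                        ga.add_edge(a, n)

    for a0 in sorted(ga):
        for b0 in sorted(gb):
            if not match_elements or ea[a0] == eb[b0]:
                extend({a0: b0}, [])
    return AtomMap(sorted(best.items()))
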