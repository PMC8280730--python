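"""Molecular graph and bonded-term data model.

A :class:`Topology` holds atoms, covalent connectivity and the five kinds of
bonded energy terms used by CHARMM-family force fields:

* bond stretch         ``E = k (b - b0)^2``            k in kcal/(mol A^2)
* angle bend           ``E = k (theta - theta0)^2``    k in kcal/(mol rad^2)
* Urey-Bradley (1-3)   ``E = k (s - s0)^2``            k in kcal/(mol A^2)
* proper dihedral      ``E = k (1 + cos(n phi - d))``  k in kcal/mol
* improper dihedral    ``E = k (psi - psi0)^2``        k in kcal/(mol rad^2)

A periodicity of ``n = 0`` marks a *harmonic* dihedral ``E = k (phi - phi0)^2``
(the "apply a harmonic potential to the dihedral angle" option for anchoring
dummy groups).  No 1/2 prefactors are used anywhere, matching the CHARMM
convention.  Angles, phases and equilibrium dihedral values are stored in
degrees at every public boundary; the molecular-mechanics engine converts to
radians internally.

Terms are identified by canonical tuples of atom ids, so that the same
physical term is never stored twice and edit plans can reference terms by
name (e.g. ``D_C-N-C1``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Atom",
    "BondTerm",
    "AngleTerm",
    "UreyBradleyTerm",
    "DihedralTerm",
    "ImproperTerm",
    "Topology",
    "GenericParams",
    "ParameterError",
    "TopologyError",
    "enumerate_terms",
    "nonredundant_dof",
    "read_molecule",
    "read_topology",
    "write_topology",
]


class TopologyError(ValueError):
    """Raised for malformed topologies or term lists."""


class ParameterError(KeyError):
    """Raised when the parameter assigner has no entry for a term pattern."""


# --------------------------------------------------------------------------
# atoms and terms
# --------------------------------------------------------------------------

#: atomic masses (amu) for the elements the package handles
MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904,
}


@dataclass
class Atom:
    """One particle of a topology.

    ``id`` doubles as the human-readable label (unique within a topology);
    ``name`` defaults to it.  ``is_dummy`` marks alchemical placeholder atoms
    in hybrid topologies; dummies keep their element (and mass) but never
    participate in nonbonded interactions.
    """

    id: str
    element: str
    name: str = ""
    coords: tuple[float, float, float] | None = None
    charge: float = 0.0
    lj_params: tuple[float, float] | None = None  # (epsilon kcal/mol, rmin/2 A)
    is_dummy: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id
        if self.element not in MASSES:
            raise TopologyError(f"unknown element {self.element!r} for atom {self.id!r}")

    @property
    def mass(self) -> float:
        return MASSES[self.element]


def _canon_bond(atoms: Sequence[str]) -> tuple[str, str]:
    a, b = atoms
    return (a, b) if a <= b else (b, a)


def _canon_angle(atoms: Sequence[str]) -> tuple[str, str, str]:
    i, j, k = atoms
    return (i, j, k) if i <= k else (k, j, i)


def _canon_dihedral(atoms: Sequence[str]) -> tuple[str, str, str, str]:
    t = tuple(atoms)
    r = t[::-1]
    return t if t <= r else r


@dataclass(frozen=True)
class BondTerm:
    atoms: tuple[str, str]
    k: float
    b0: float

    def __post_init__(self):
        object.__setattr__(self, "atoms", _canon_bond(self.atoms))
        if self.k < 0:
            raise TopologyError(f"negative force constant on bond {self.atoms}")

    @property
    def params(self) -> tuple:
        return (self.k, self.b0)


@dataclass(frozen=True)
class AngleTerm:
    """Harmonic valence angle; ``atoms = (i, center, k)``, theta0 in degrees."""

    atoms: tuple[str, str, str]
    k: float
    theta0: float

    def __post_init__(self):
        object.__setattr__(self, "atoms", _canon_angle(self.atoms))
        if self.k < 0:
            raise TopologyError(f"negative force constant on angle {self.atoms}")

    @property
    def center(self) -> str:
        return self.atoms[1]

    @property
    def outer(self) -> tuple[str, str]:
        return (self.atoms[0], self.atoms[2])

    @property
    def params(self) -> tuple:
        return (self.k, self.theta0)


@dataclass(frozen=True)
class UreyBradleyTerm:
    """Harmonic 1-3 distance term over the outer atoms of an angle."""

    atoms: tuple[str, str]
    k: float
    s0: float

    def __post_init__(self):
        object.__setattr__(self, "atoms", _canon_bond(self.atoms))

    @property
    def params(self) -> tuple:
        return (self.k, self.s0)


@dataclass(frozen=True)
class DihedralTerm:
    """Proper dihedral over a bonded path i-j-k-l.

    ``n >= 1``: periodic CHARMM form with phase ``delta`` (degrees).
    ``n == 0``: harmonic dihedral, ``delta`` is the equilibrium value phi0.
    """

    atoms: tuple[str, str, str, str]
    k: float
    n: int
    delta: float

    def __post_init__(self):
        object.__setattr__(self, "atoms", _canon_dihedral(self.atoms))
        if self.n < 0 or self.n != int(self.n):
            raise TopologyError(f"dihedral periodicity must be a non-negative integer, got {self.n}")
        if self.k < 0:
            raise TopologyError(f"negative force constant on dihedral {self.atoms}")

    @property
    def central_bond(self) -> tuple[str, str]:
        return _canon_bond(self.atoms[1:3])

    @property
    def params(self) -> tuple:
        return (self.k, self.n, self.delta)


@dataclass(frozen=True)
class ImproperTerm:
    """Harmonic improper dihedral; first atom is the center, psi0 in degrees."""

    atoms: tuple[str, str, str, str]
    k: float
    psi0: float

    def __post_init__(self):
        # center stays first; peripheral atoms sorted for a canonical identity
        c, *rest = self.atoms
        object.__setattr__(self, "atoms", (c, *sorted(rest)))

    @property
    def params(self) -> tuple:
        return (self.k, self.psi0)


Term = BondTerm | AngleTerm | UreyBradleyTerm | DihedralTerm | ImproperTerm

_TERM_KINDS = {
    BondTerm: "bond",
    AngleTerm: "angle",
    UreyBradleyTerm: "ureybradley",
    DihedralTerm: "dihedral",
    ImproperTerm: "improper",
}


def term_kind(term: Term) -> str:
    return _TERM_KINDS[type(term)]


def term_label(term: Term) -> str:
    """Human-readable canonical label, e.g. ``D_C-N-C1``."""
    return "-".join(term.atoms)


# --------------------------------------------------------------------------
# topology container
# --------------------------------------------------------------------------


@dataclass
class Topology:
    """Atoms, connectivity and the full bonded-term lists of one molecule.

    ``exclusions`` marks the nonbonded policy: 1-2 and 1-3 pairs excluded,
    1-4 pairs scaled by ``scale14`` (only relevant when the optional
    intramolecular nonbonded terms are switched on in the MM engine).
    """

    atoms: dict[str, Atom] = field(default_factory=dict)
    bonds: list[tuple[str, str]] = field(default_factory=list)
    bond_terms: list[BondTerm] = field(default_factory=list)
    angle_terms: list[AngleTerm] = field(default_factory=list)
    urey_bradley_terms: list[UreyBradleyTerm] = field(default_factory=list)
    dihedral_terms: list[DihedralTerm] = field(default_factory=list)
    improper_terms: list[ImproperTerm] = field(default_factory=list)
    scale14: float = 1.0

    # -- construction -------------------------------------------------------

    def add_atom(self, atom: Atom) -> None:
        if atom.id in self.atoms:
            raise TopologyError(f"duplicate atom id {atom.id!r}")
        self.atoms[atom.id] = atom

    def add_bond(self, a: str, b: str) -> None:
        for x in (a, b):
            if x not in self.atoms:
                raise TopologyError(f"bond references unknown atom {x!r}")
        e = _canon_bond((a, b))
        if e in self.bonds:
            raise TopologyError(f"duplicate bond {e}")
        self.bonds.append(e)

    # -- views --------------------------------------------------------------

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.atoms)
        g.add_edges_from(self.bonds)
        return g

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_ids(self) -> list[str]:
        return list(self.atoms)

    def all_terms(self) -> list[Term]:
        return (
            list(self.bond_terms)
            + list(self.angle_terms)
            + list(self.urey_bradley_terms)
            + list(self.dihedral_terms)
            + list(self.improper_terms)
        )

    def dummy_atoms(self) -> set[str]:
        return {a.id for a in self.atoms.values() if a.is_dummy}

    def coords_array(self) -> np.ndarray:
        if any(a.coords is None for a in self.atoms.values()):
            raise TopologyError("topology has no complete coordinate set")
        return np.array([self.atoms[i].coords for i in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        for a, xyz in zip(self.atoms.values(), coords):
            a.coords = tuple(float(v) for v in xyz)

    def copy(self) -> "Topology":
        t = Topology(scale14=self.scale14)
        for a in self.atoms.values():
            t.atoms[a.id] = replace(a)
        t.bonds = list(self.bonds)
        t.bond_terms = list(self.bond_terms)
        t.angle_terms = list(self.angle_terms)
        t.urey_bradley_terms = list(self.urey_bradley_terms)
        t.dihedral_terms = list(self.dihedral_terms)
        t.improper_terms = list(self.improper_terms)
        return t

    # -- validation ---------------------------------------------------------

    def validate(self, require_connected: bool = True,
                 check_coords: bool = True) -> None:
        """Check the structural invariants; raise :class:`TopologyError`."""
        with_coords = [a for a in self.atoms.values() if a.coords is not None]
        if check_coords and with_coords and len(with_coords) != self.n_atoms:
            raise TopologyError("coordinates must be present for all atoms or none")
        g = self.graph()
        if require_connected and self.n_atoms and not nx.is_connected(g):
            raise TopologyError("connectivity graph is not a single connected molecule")
        seen: set[tuple] = set()
        for term in self.all_terms():
            for a in term.atoms:
                if a not in self.atoms:
                    raise TopologyError(f"term {term_label(term)} references unknown atom {a!r}")
            key = (term_kind(term), term.atoms)
            if key in seen:
                raise TopologyError(f"duplicate {term_kind(term)} term {term_label(term)}")
            seen.add(key)
        for t in self.angle_terms:
            i, c, k = t.atoms
            if not (g.has_edge(i, c) and g.has_edge(c, k)):
                raise TopologyError(f"angle {term_label(t)} center is not bonded to both flanks")
        for t in self.dihedral_terms:
            a, b, c, d = t.atoms
            if not (g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(c, d)):
                raise TopologyError(f"dihedral {term_label(t)} is not a bonded path")
        angle_pairs = {frozenset(t.outer) for t in self.angle_terms}
        for t in self.urey_bradley_terms:
            if frozenset(t.atoms) not in angle_pairs:
                raise TopologyError(
                    f"Urey-Bradley {term_label(t)} does not span the outer atoms of any angle"
                )

    def find_term(self, kind: str, atoms: Sequence[str]) -> Term | None:
        lists = {
            "bond": self.bond_terms,
            "angle": self.angle_terms,
            "ureybradley": self.urey_bradley_terms,
            "dihedral": self.dihedral_terms,
            "improper": self.improper_terms,
        }
        canon = {
            "bond": _canon_bond,
            "angle": _canon_angle,
            "ureybradley": _canon_bond,
            "dihedral": _canon_dihedral,
            "improper": lambda a: (a[0], *sorted(a[1:])),
        }[kind](tuple(atoms))
        for t in lists[kind]:
            if t.atoms == canon:
                return t
        return None


# --------------------------------------------------------------------------
# term enumeration
# --------------------------------------------------------------------------


def enumerate_angles(g: nx.Graph) -> list[tuple[str, str, str]]:
    """All unordered bonded triples i-c-k with a common center c."""
    out = []
    for c in sorted(g.nodes):
        nbrs = sorted(g.neighbors(c))
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                out.append(_canon_angle((nbrs[a], c, nbrs[b])))
    return out

def enumerate_dihedrals(g: nx.Graph) -> list[tuple[str, str, str, str]]:
    """All simple bonded 4-paths i-j-k-l, each counted once.

    A path traversed in both directions is one dihedral; 3-membered rings
    (where the path would revisit an atom) are rejected upstream.
    """
    seen: set[tuple] = set()
    out = []
    for j, k in sorted(tuple(sorted(e)) for e in g.edges):
        for i in sorted(g.neighbors(j)):
            if i == k:
                continue
            for l in sorted(g.neighbors(k)):
                if l == j or l == i:
                    continue
                t = _canon_dihedral((i, j, k, l))
                if t not in seen:
                    seen.add(t)
                    out.append(t)
    return out


def nonredundant_dof(topology: Topology, collinear_tol: float = 1e-6) -> int:
    """Number of nonredundant internal degrees of freedom, 3N - 6.

    If reference coordinates are present and all atoms are collinear the
    count is 3N - 5; this case is flagged with a warning-level print rather
    than applied silently (it never occurs for the molecules handled here).
    """
    n = topology.n_atoms
    if n < 3:
        raise TopologyError("nonredundant_dof needs at least 3 atoms")
    try:
        x = topology.coords_array()
    except TopologyError:
        return 3 * n - 6
    centered = x - x.mean(axis=0)
    # collinear iff the two smallest singular values vanish
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < collinear_tol and s[0] > 0:
        import warnings

        warnings.warn("all atoms collinear: using 3N - 5 degrees of freedom")
        return 3 * n - 5
    return 3 * n - 6


ParameterAssigner = Callable[[str, tuple[str, ...], nx.Graph, Mapping[str, str]], tuple | None]


class GenericParams:
    """Built-in generic bonded parameter set.

    The study's CGenFF parameters are not published, so a transparent generic
    set is used: all acceptance-grade results of this package (dummy counts,
    edit-plan term sets, modification counts, separability verdicts) are
    independent of the numerical values; the gas-phase checks only need
    qualitatively correct stiffnesses.

    * bonds: k = 300 kcal/(mol A^2), b0 by element pair; conjugated
      (sp2-sp2) carbon/nitrogen bonds use the aromatic 1.39 A so that
      six-membered aromatic rings close as regular, strain-free hexagons
    * angles: k = 50 kcal/(mol rad^2), theta0 109.5 deg (sp3 center),
      120 deg (sp2 center), 106.7 deg for a pyramidal amine nitrogen
      (so that alkane-derived dummy angles genuinely differ from the
      amine's own equilibrium, as they do in real force fields)
    * dihedrals: k = 0.2 kcal/mol, n = 3 (saturated central bond) or n = 2
      (conjugated central bond, phase 180 deg)

    Hybridization is inferred from element + degree (C with 3 neighbors and
    N with 2 neighbors are sp2, a 1-coordinate O is a carbonyl oxygen);
    explicit overrides can be given per atom id.
    """

    BOND_B0 = {
        frozenset({"C"}): 1.53,
        frozenset({"C", "H"}): 1.09,
        frozenset({"N", "H"}): 1.01,
        frozenset({"O", "H"}): 0.96,
        frozenset({"C", "N"}): 1.34,
        frozenset({"C", "O"}): 1.41,
        frozenset({"H"}): 1.09,  # arises only transiently in hybrid bookkeeping
    }
    AROMATIC_B0 = 1.39  # sp2-sp2 C/N bonds (ring closure without strain)
    AMINE_THETA0 = 106.7

    def __init__(self, hybridization: Mapping[str, str] | None = None,
                 with_urey_bradley: bool = False):
        self.hybridization = dict(hybridization or {})
        self.with_urey_bradley = with_urey_bradley

    def hyb(self, atom: str, g: nx.Graph, elements: Mapping[str, str]) -> str:
        if atom in self.hybridization:
            return self.hybridization[atom]
        e, d = elements[atom], g.degree(atom)
        if e == "C" and d == 3:
            return "sp2"
        if e == "N" and d == 2:
            return "sp2"
        if e == "O" and d == 1:
            return "sp2"
        return "sp3"

    def __call__(self, kind: str, atoms: tuple[str, ...], g: nx.Graph,
                 elements: Mapping[str, str]) -> tuple | None:
        if kind == "bond":
            a, b = atoms
            pair = frozenset({elements[a], elements[b]})
            if pair not in self.BOND_B0:
                raise ParameterError(
                    f"no generic bond parameters for element pair {sorted(pair)}"
                )
            if (pair <= {"C", "N"} and self.hyb(a, g, elements) == "sp2"
                    and self.hyb(b, g, elements) == "sp2"):
                return (300.0, self.AROMATIC_B0)
            return (300.0, self.BOND_B0[pair])
        if kind == "angle":
            c = atoms[1]
            if self.hyb(c, g, elements) == "sp2":
                theta0 = 120.0
            elif elements[c] == "N":
                theta0 = self.AMINE_THETA0
            else:
                theta0 = 109.5
            return (50.0, theta0)
        if kind == "ureybradley":
            if not self.with_urey_bradley:
                return None
            i, c, k = atoms  # UB pattern is resolved from the parent angle
            theta0 = 120.0 if self.hyb(c, g, elements) == "sp2" else 109.5
            bi = self.BOND_B0.get(frozenset({elements[i], elements[c]}), 1.4)
            bk = self.BOND_B0.get(frozenset({elements[k], elements[c]}), 1.4)
            s0 = math.sqrt(bi * bi + bk * bk - 2 * bi * bk * math.cos(math.radians(theta0)))
            return (30.0, s0)
        if kind == "dihedral":
            j, k = atoms[1], atoms[2]
            conj = self.hyb(j, g, elements) == "sp2" and self.hyb(k, g, elements) == "sp2"
            # conjugated torsions are much stiffer than alkane ones; 1.5
            # kcal/mol keeps rings planar and gives the 2-fold substituent
            # torsion a barrier (2k = 3 kcal/mol) that a dummy group crosses
            # many times in a sub-nanosecond gas-phase run
            return (1.5, 2, 180.0) if conj else (0.2, 3, 0.0)
        raise ParameterError(f"unknown term kind {kind!r}")


def enumerate_terms(topology: Topology, assigner: ParameterAssigner | None = None) -> None:
    """Populate the bonded-term lists of ``topology`` from its connectivity.

    Bonds become bond terms, every bonded triple with a common center becomes
    an angle term, every simple bonded 4-path a dihedral term.  The assigner
    supplies parameters per pattern (``None`` means "no term of this kind for
    this pattern", used for the optional Urey-Bradley set).  Enumeration is
    idempotent: running it twice yields identical term lists.
    """
    assigner = assigner or GenericParams()
    g = topology.graph()
    for cyc in nx.cycle_basis(g):
        if len(cyc) == 3:
            raise TopologyError("3-membered rings are not supported")
    elements = {a.id: a.element for a in topology.atoms.values()}

    topology.bond_terms = [
        BondTerm(e, *assigner("bond", e, g, elements)) for e in sorted(topology.bonds)
    ]
    topology.angle_terms = [
        AngleTerm(t, *assigner("angle", t, g, elements)) for t in enumerate_angles(g)
    ]
    ubs = []
    for t in enumerate_angles(g):
        p = assigner("ureybradley", t, g, elements)
        if p is not None:
            ubs.append(UreyBradleyTerm((t[0], t[2]), *p))
    topology.urey_bradley_terms = ubs
    topology.dihedral_terms = [
        DihedralTerm(t, *assigner("dihedral", t, g, elements))
        for t in enumerate_dihedrals(g)
    ]
    topology.improper_terms = []
    topology.validate()


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------


def _term_to_json(term: Term) -> dict:
    d = {"atoms": list(term.atoms)}
    if isinstance(term, BondTerm):
        d.update(k=term.k, b0=term.b0)
    elif isinstance(term, AngleTerm):
        d.update(k=term.k, theta0=term.theta0)
    elif isinstance(term, UreyBradleyTerm):
        d.update(k=term.k, s0=term.s0)
    elif isinstance(term, DihedralTerm):
        d.update(k=term.k, n=term.n, delta=term.delta)
    elif isinstance(term, ImproperTerm):
        d.update(k=term.k, psi0=term.psi0)
    return d


def topology_to_json(topology: Topology) -> dict:
    atoms = []
    for a in topology.atoms.values():
        rec: dict = {"id": a.id, "element": a.element, "name": a.name}
        if a.coords is not None:
            rec["coords"] = list(a.coords)
        if a.charge:
            rec["charge"] = a.charge
        if a.lj_params is not None:
            rec["lj_params"] = list(a.lj_params)
        if a.is_dummy:
            rec["is_dummy"] = True
        atoms.append(rec)
    return {
        "atoms": atoms,
        "bonds": [list(b) for b in topology.bonds],
        "bond_terms": [_term_to_json(t) for t in topology.bond_terms],
        "angles": [_term_to_json(t) for t in topology.angle_terms],
        "ureybradley": [_term_to_json(t) for t in topology.urey_bradley_terms],
        "dihedrals": [_term_to_json(t) for t in topology.dihedral_terms],
        "impropers": [_term_to_json(t) for t in topology.improper_terms],
        "scale14": topology.scale14,
    }


def topology_from_json(data: Mapping) -> Topology:
    top = Topology(scale14=float(data.get("scale14", 1.0)))
    for rec in data["atoms"]:
        top.add_atom(
            Atom(
                id=rec["id"],
                element=rec["element"],
                name=rec.get("name", rec["id"]),
                coords=tuple(rec["coords"]) if rec.get("coords") is not None else None,
                charge=float(rec.get("charge", 0.0)),
                lj_params=tuple(rec["lj_params"]) if rec.get("lj_params") else None,
                is_dummy=bool(rec.get("is_dummy", False)),
            )
        )
    for b in data.get("bonds", []):
        top.add_bond(*b)
    top.bond_terms = [BondTerm(tuple(t["atoms"]), t["k"], t["b0"]) for t in data.get("bond_terms", [])]
    top.angle_terms = [AngleTerm(tuple(t["atoms"]), t["k"], t["theta0"]) for t in data.get("angles", [])]
    top.urey_bradley_terms = [
        UreyBradleyTerm(tuple(t["atoms"]), t["k"], t["s0"]) for t in data.get("ureybradley", [])
    ]
    top.dihedral_terms = [
        DihedralTerm(tuple(t["atoms"]), t["k"], int(t["n"]), t["delta"])
        for t in data.get("dihedrals", [])
    ]
    top.improper_terms = [
        ImproperTerm(tuple(t["atoms"]), t["k"], t["psi0"]) for t in data.get("impropers", [])
    ]
    top.validate(require_connected=False)
    return top


def write_topology(topology: Topology, path) -> None:
    with open(path, "w") as fh:
        json.dump(topology_to_json(topology), fh, indent=1)


def read_topology(path) -> Topology:
    with open(path) as fh:
        return topology_from_json(json.load(fh))


def read_molecule(path, fmt: str | None = None,
                  assigner: ParameterAssigner | None = None) -> Topology:
    """Read a molecule from SDF/MOL (V2000) or native topology-JSON.

    SDF import takes elements, bonds and coordinates from the file and then
    enumerates bonded terms with the active parameter set.  The format is
    inferred from the file suffix when not given.
    """
    p = str(path)
    if fmt is None:
        fmt = "json" if p.endswith(".json") else "sdf"
    if fmt == "json":
        return read_topology(p)
    if fmt not in ("sdf", "mol"):
        raise ValueError(f"unknown format {fmt!r}")
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading SDF/MOL files requires rdkit") from exc
    mol = Chem.MolFromMolFile(p, removeHs=False, sanitize=False)
    if mol is None:
        raise TopologyError(f"malformed MOL/SDF file: {p}")
    top = Topology()
    conf = mol.GetConformer() if mol.GetNumConformers() else None
    counts: dict[str, int] = {}
    names = []
    for at in mol.GetAtoms():
        e = at.GetSymbol()
        counts[e] = counts.get(e, 0) + 1
        names.append(f"{e}{counts[e]}")
    for idx, at in enumerate(mol.GetAtoms()):
        xyz = None
        if conf is not None:
            pos = conf.GetAtomPosition(idx)
            xyz = (pos.x, pos.y, pos.z)
        top.add_atom(Atom(id=names[idx], element=at.GetSymbol(), coords=xyz))
    for b in mol.GetBonds():
        top.add_bond(names[b.GetBeginAtomIdx()], names[b.GetEndAtomIdx()])
    g = top.graph()
    if top.n_atoms and not nx.is_connected(g):
        raise TopologyError(f"{p}: file contains more than one molecule")
    enumerate_terms(top, assigner)
    return top
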