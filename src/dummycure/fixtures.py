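"""Programmatic construction of the benchmark transformation fixtures.

Twelve pairs of small solutes (alkanes, alcohols, amines, aromatics and the
two tautomer pairs), their atom maps, hybrid topologies and reference
geometries, built entirely from internal templates -- nothing is downloaded
and no binary data is stored.  Every fixture is deterministic: molecules are
assembled from idealized internal coordinates and then minimized in the
package's generic force field, and dummy-atom coordinates are transplanted
from the partner end state by least-squares superposition of the mapped
core.

The 24 labels cover the transformations at different curation settings
(best-practice vs naive, two-angles vs dihedral anchoring of dual junctions,
soft calibrated angles at nonplanar triple junctions, and a dual-topology
hybrid for the acetone / 2-propenol tautomerism).  Atom naming follows the
benchmark figures (H32, D_C5, C1...C5, D_C, D_H1, ...) so that printed edit
plans read like the published tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alchemy import AtomMap, DummyPartition, Junction, build_hybrid, classify_junctions, partition_dummies
from .curation import CurationOptions, EditPlan, curate
from .molgraph import Atom, GenericParams, Topology, enumerate_terms

__all__ = [
    "FixturePair",
    "FIXTURE_LABELS",
    "build_fixture",
    "expected_plan",
    "curate_fixture",
]


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------


def _unit(v):
    return v / np.linalg.norm(v)


def _nerf(c, b, a, r, theta_deg, phi_deg):
    """Place X bonded to c with angle X-c-b and dihedral X-c-b-a."""
    theta = np.radians(theta_deg)
    phi = np.radians(phi_deg)
    bc = _unit(c - b)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:  # collinear reference; pick any perpendicular
        n = np.cross(bc, [0.0, 0.0, 1.0])
        if np.linalg.norm(n) < 1e-9:
            n = np.cross(bc, [0.0, 1.0, 0.0])
        nn = np.linalg.norm(n)
    n = n / nn
    m = np.cross(n, bc)
    d = np.array([-r * np.cos(theta),
                  r * np.sin(theta) * np.cos(phi),
                  r * np.sin(theta) * np.sin(phi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


class _Mol:
    """Tiny internal-coordinate molecule builder."""

    def __init__(self):
        self.elements: dict[str, str] = {}
        self.bonds: list[tuple[str, str]] = []
        self.xyz: dict[str, np.ndarray] = {}

    def add(self, name, element, refs=(), r=1.0, theta=109.5, phi=180.0,
            xyz=None, bond=True):
        self.elements[name] = element
        if xyz is not None:
            self.xyz[name] = np.asarray(xyz, float)
        elif len(refs) == 0:
            self.xyz[name] = np.zeros(3)
        elif len(refs) == 1:
            self.xyz[name] = self.xyz[refs[0]] + np.array([r, 0.0, 0.0])
        elif len(refs) == 2:
            c, b = (self.xyz[x] for x in refs)
            e1 = _unit(b - c)
            e2 = np.cross(e1, [0.0, 0.0, 1.0])
            if np.linalg.norm(e2) < 1e-9:
                e2 = np.cross(e1, [0.0, 1.0, 0.0])
            e2 = _unit(e2)
            th = np.radians(theta)
            self.xyz[name] = c + r * (np.cos(th) * e1 + np.sin(th) * e2)
        else:
            c, b, a = (self.xyz[x] for x in refs[:3])
            self.xyz[name] = _nerf(c, b, a, r, theta, phi)
        if bond and refs:
            self.bonds.append((name, refs[0]))

    def add_bond(self, a, b):
        self.bonds.append((a, b))

    def topology(self, minimize_geometry: bool = True) -> Topology:
        top = Topology()
        for name, elem in self.elements.items():
            top.add_atom(Atom(id=name, element=elem,
                              coords=tuple(self.xyz[name])))
        for a, b in self.bonds:
            top.add_bond(a, b)
        enumerate_terms(top, GenericParams())
        if minimize_geometry:
            from .mm import EnergyModel, minimize

            x, _, _ = minimize(EnergyModel(top), top.coords_array())
            top.set_coords(x)
        return top


# --------------------------------------------------------------------------
# molecule templates
# --------------------------------------------------------------------------

_B = {"CC": 1.53, "CH": 1.09, "NH": 1.01, "OH": 0.96, "CN": 1.34, "CO": 1.41}
TD = 109.5


def _alkane(n: int, h32_anti: bool = False) -> _Mol:
    """n-alkane C1..Cn.  ``h32_anti`` renames the terminal hydrogens of the
    last carbon so that the anti one is H{n}2 (the bridge-atom convention
    of the hexane-to-propane benchmark)."""
    m = _Mol()
    m.add("C1", "C")
    m.add("C2", "C", ("C1",), _B["CC"])
    if n >= 3:
        m.add("C3", "C", ("C2", "C1"), _B["CC"], TD)
    for i in range(4, n + 1):
        m.add(f"C{i}", "C", (f"C{i-1}", f"C{i-2}", f"C{i-3}"), _B["CC"], TD, 180.0)
    # hydrogens on C1
    if n >= 3:
        for h, phi in (("H11", 180.0), ("H12", 60.0), ("H13", -60.0)):
            m.add(h, "H", ("C1", "C2", "C3"), _B["CH"], TD, phi)
    else:  # ethane
        m.add("H11", "H", ("C1", "C2"), _B["CH"], TD)
        m.add("H12", "H", ("C1", "C2", "H11"), _B["CH"], TD, 120.0)
        m.add("H13", "H", ("C1", "C2", "H11"), _B["CH"], TD, -120.0)
        for h, phi in (("H21", 60.0), ("H22", 180.0), ("H23", -60.0)):
            m.add(h, "H", ("C2", "C1", "H11"), _B["CH"], TD, phi)
        return m
    # interior carbons
    for i in range(2, n):
        refs = (f"C{i}", f"C{i-1}", f"C{i+1}")
        m.add(f"H{i}1", "H", refs, _B["CH"], TD, 120.0)
        m.add(f"H{i}2", "H", refs, _B["CH"], TD, -120.0)
    # terminal carbon Cn
    refs = (f"C{n}", f"C{n-1}", f"C{n-2}")
    if h32_anti:
        order = ((f"H{n}1", 60.0), (f"H{n}2", 180.0), (f"H{n}3", -60.0))
    else:
        order = ((f"H{n}1", 180.0), (f"H{n}2", 60.0), (f"H{n}3", -60.0))
    for h, phi in order:
        m.add(h, "H", refs, _B["CH"], TD, phi)
    return m


def methane() -> _Mol:
    m = _Mol()
    m.add("C", "C")
    m.add("H1", "H", ("C",), _B["CH"])
    m.add("H2", "H", ("C", "H1"), _B["CH"], TD)
    m.add("H3", "H", ("C", "H1", "H2"), _B["CH"], TD, 120.0)
    m.add("H4", "H", ("C", "H1", "H2"), _B["CH"], TD, -120.0)
    return m


def water() -> _Mol:
    m = _Mol()
    m.add("O", "O")
    m.add("H1", "H", ("O",), _B["OH"])
    m.add("H2", "H", ("O", "H1"), _B["OH"], TD)
    return m


def ammonia() -> _Mol:
    m = _Mol()
    m.add("N", "N")
    m.add("H1", "H", ("N",), _B["NH"])
    m.add("H2", "H", ("N", "H1"), _B["NH"], TD)
    m.add("H3", "H", ("N", "H1", "H2"), _B["NH"], TD, 115.0)
    return m


def methanol() -> _Mol:
    m = _Mol()
    m.add("C", "C")
    m.add("O", "O", ("C",), _B["CO"])
    m.add("HO", "H", ("O", "C"), _B["OH"], TD)
    m.add("H1", "H", ("C", "O", "HO"), _B["CH"], TD, 180.0)
    m.add("H2", "H", ("C", "O", "HO"), _B["CH"], TD, 60.0)
    m.add("H3", "H", ("C", "O", "HO"), _B["CH"], TD, -60.0)
    return m


def methylamine() -> _Mol:
    m = _Mol()
    m.add("C", "C")
    m.add("N", "N", ("C",), _B["CN"])
    m.add("HC1", "H", ("C", "N"), _B["CH"], TD)
    m.add("HC2", "H", ("C", "N", "HC1"), _B["CH"], TD, 120.0)
    m.add("HC3", "H", ("C", "N", "HC1"), _B["CH"], TD, -120.0)
    m.add("HN1", "H", ("N", "C", "HC1"), _B["NH"], TD, 180.0)
    m.add("HN2", "H", ("N", "C", "HC1"), _B["NH"], TD, 60.0)
    return m


def dimethyl_ether() -> _Mol:
    m = _Mol()
    m.add("O", "O")
    m.add("C1", "C", ("O",), _B["CO"])
    m.add("C2", "C", ("O", "C1"), _B["CO"], TD)
    for c, other in (("C1", "C2"), ("C2", "C1")):
        i = c[1]
        m.add(f"H{i}1", "H", (c, "O", other), _B["CH"], TD, 180.0)
        m.add(f"H{i}2", "H", (c, "O", other), _B["CH"], TD, 60.0)
        m.add(f"H{i}3", "H", (c, "O", other), _B["CH"], TD, -60.0)
    return m


def propanol() -> _Mol:
    m = _Mol()
    m.add("C1", "C")
    m.add("C2", "C", ("C1",), _B["CC"])
    m.add("C3", "C", ("C2", "C1"), _B["CC"], TD)
    m.add("O", "O", ("C3", "C2", "C1"), _B["CO"], TD, 180.0)
    m.add("HO", "H", ("O", "C3", "C2"), _B["OH"], TD, 180.0)
    for h, phi in (("H11", 180.0), ("H12", 60.0), ("H13", -60.0)):
        m.add(h, "H", ("C1", "C2", "C3"), _B["CH"], TD, phi)
    m.add("H21", "H", ("C2", "C1", "C3"), _B["CH"], TD, 120.0)
    m.add("H22", "H", ("C2", "C1", "C3"), _B["CH"], TD, -120.0)
    m.add("H31", "H", ("C3", "C2", "O"), _B["CH"], TD, 120.0)
    m.add("H32", "H", ("C3", "C2", "O"), _B["CH"], TD, -120.0)
    return m


def acetone() -> _Mol:
    m = _Mol()
    m.add("C2", "C")
    m.add("C1", "C", ("C2",), _B["CC"])
    m.add("C3", "C", ("C2", "C1"), _B["CC"], 120.0)
    m.add("O", "O", ("C2", "C1", "C3"), _B["CO"], 120.0, 180.0)
    for c in ("C1", "C3"):
        i = c[1]
        for h, phi in ((f"H{i}1", 0.0), (f"H{i}2", 120.0), (f"H{i}3", -120.0)):
            m.add(h, "H", (c, "C2", "O"), _B["CH"], TD, phi)
    return m


def propenol() -> _Mol:
    """2-propenol, the enol tautomer of acetone: CH2=C(OH)-CH3."""
    m = _Mol()
    m.add("C2", "C")
    m.add("C1", "C", ("C2",), _B["CC"])
    m.add("C3", "C", ("C2", "C1"), _B["CC"], 120.0)
    m.add("O", "O", ("C2", "C1", "C3"), _B["CO"], 120.0, 180.0)
    m.add("H", "H", ("O", "C2", "C1"), _B["OH"], TD, 180.0)
    m.add("H11", "H", ("C1", "C2", "O"), _B["CH"], 120.0, 0.0)
    m.add("H12", "H", ("C1", "C2", "O"), _B["CH"], 120.0, 180.0)
    for h, phi in (("H31", 180.0), ("H32", 60.0), ("H33", -60.0)):
        m.add(h, "H", ("C3", "C2", "O"), _B["CH"], TD, phi)
    return m


def _hexagon(names: list[str]) -> dict[str, np.ndarray]:
    r = 1.53  # hexagon side equals the generic C-C bond length
    out = {}
    for i, name in enumerate(names):
        ang = np.radians(60.0 * i)
        out[name] = np.array([r * np.cos(ang), r * np.sin(ang), 0.0])
    return out


def _ring_substituent(pos, center, bond_length):
    return pos[center] + bond_length * _unit(pos[center])


def toluene() -> _Mol:
    m = _Mol()
    ring = ["C1", "C2", "C3", "C4", "C5", "C6"]
    pos = _hexagon(ring)
    for i, c in enumerate(ring):
        m.add(c, "C", xyz=pos[c])
        if i:
            m.add_bond(c, ring[i - 1])
    m.add_bond("C6", "C1")
    m.add("C", "C", xyz=_ring_substituent(pos, "C1", _B["CC"]))
    m.add_bond("C", "C1")
    for c in ring[1:]:
        m.add(f"HR{c[1]}", "H", xyz=_ring_substituent(pos, c, _B["CH"]))
        m.add_bond(f"HR{c[1]}", c)
    m.add("H1", "H", ("C", "C1", "C2"), _B["CH"], TD, 90.0)
    m.add("H2", "H", ("C", "C1", "C2"), _B["CH"], TD, 210.0)
    m.add("H3", "H", ("C", "C1", "C2"), _B["CH"], TD, -30.0)
    return m


def pyridine() -> _Mol:
    m = _Mol()
    ring = ["N", "C1", "C2", "C3", "C4", "C5"]
    pos = _hexagon(ring)
    for i, a in enumerate(ring):
        m.add(a, "N" if a == "N" else "C", xyz=pos[a])
        if i:
            m.add_bond(a, ring[i - 1])
    m.add_bond("C5", "N")
    for c in ring[1:]:
        m.add(f"H{c[1]}", "H", xyz=_ring_substituent(pos, c, _B["CH"]))
        m.add_bond(f"H{c[1]}", c)
    return m


def phenol() -> _Mol:
    m = _Mol()
    ring = ["C1", "C2", "C3", "C4", "C5", "C6"]
    pos = _hexagon(ring)
    for i, c in enumerate(ring):
        m.add(c, "C", xyz=pos[c])
        if i:
            m.add_bond(c, ring[i - 1])
    m.add_bond("C6", "C1")
    m.add("O", "O", xyz=_ring_substituent(pos, "C1", _B["CO"]))
    m.add_bond("O", "C1")
    for c in ring[1:]:
        m.add(f"H{c[1]}", "H", xyz=_ring_substituent(pos, c, _B["CH"]))
        m.add_bond(f"H{c[1]}", c)
    m.add("HO", "H", ("O", "C1", "C2"), _B["OH"], TD, 0.0)
    return m


def cyclohexadienone() -> _Mol:
    """Cyclohexa-2,4-dien-1-one: carbonyl at C1, sp3 CH2 at C6."""
    m = _Mol()
    ring = ["C1", "C2", "C3", "C4", "C5", "C6"]
    pos = _hexagon(ring)
    for i, c in enumerate(ring):
        m.add(c, "C", xyz=pos[c])
        if i:
            m.add_bond(c, ring[i - 1])
    m.add_bond("C6", "C1")
    m.add("O", "O", xyz=_ring_substituent(pos, "C1", _B["CO"]))
    m.add_bond("O", "C1")
    for c in ring[1:5]:
        m.add(f"H{c[1]}", "H", xyz=_ring_substituent(pos, c, _B["CH"]))
        m.add_bond(f"H{c[1]}", c)
    m.add("H6", "H", ("C6", "C5", "C4"), _B["CH"], TD, 120.0)
    m.add("H6b", "H", ("C6", "C5", "C4"), _B["CH"], TD, -120.0)
    return m


# --------------------------------------------------------------------------
# dummy coordinate transplant
# --------------------------------------------------------------------------


def _transplant_dummy_coords(hybrid: Topology, source: Topology,
                             source_to_hybrid: dict[str, str]) -> None:
    """Fill dummy coordinates by superposing the source end state's mapped
    core onto the hybrid's physical coordinates (Kabsch)."""
    from scipy.spatial.transform import Rotation

    mapped_src = [s for s in source_to_hybrid
                  if not hybrid.atoms[source_to_hybrid[s]].is_dummy]
    src_pts = np.array([source.atoms[s].coords for s in mapped_src])
    dst_pts = np.array([hybrid.atoms[source_to_hybrid[s]].coords for s in mapped_src])
    src_c = src_pts.mean(axis=0)
    dst_c = dst_pts.mean(axis=0)
    if len(mapped_src) >= 3:
        rot, _ = Rotation.align_vectors(dst_pts - dst_c, src_pts - src_c)
    else:  # degenerate core; translation only
        rot = Rotation.identity()
    for s, h in source_to_hybrid.items():
        atom = hybrid.atoms[h]
        if atom.is_dummy:
            p = np.asarray(source.atoms[s].coords) - src_c
            atom.coords = tuple(rot.apply(p) + dst_c)


def _relax_dummies(top: Topology) -> None:
    """Relax dummy coordinates with the physical atoms frozen, so the stored
    hybrid starts force-free on the dummy side without leaving the physical
    molecule's minimum basin."""
    from .mm import EnergyModel, minimize_subset

    model = EnergyModel(top)
    ids = list(top.atoms)
    free = np.array([top.atoms[a].is_dummy for a in ids])
    if not free.any():
        return
    top.set_coords(minimize_subset(model, top.coords_array(), free))


def _hybrid_with_coords(top_a, top_b, amap, endpoint) -> Topology:
    hyb = build_hybrid(top_a, top_b, amap, endpoint)
    source = top_a if endpoint == "B" else top_b
    pairs = amap.pairs if endpoint == "B" else [(b, a) for a, b in amap.pairs]
    trans = dict(pairs)
    for s in source.atoms:
        if s not in trans:
            trans[s] = f"D_{s}"
    _transplant_dummy_coords(hyb, source, trans)
    _relax_dummies(hyb)
    return hyb


# --------------------------------------------------------------------------
# fixture registry
# --------------------------------------------------------------------------


@dataclass
class FixturePair:
    """One transformation label: topologies, map, hybrids and expectations."""

    label: str
    pair: str
    top_a: Topology
    top_b: Topology
    amap: AtomMap | None
    hybrids: dict[str, Topology]            # endpoint -> hybrid with coords
    options: dict[str, CurationOptions]     # endpoint -> curation options
    expected_n_dum: int                     # as printed per transformation
    expected_n_mod: int
    n_dum_by_endpoint: dict[str, int] = field(default_factory=dict)
    dual_topology: bool = False

    @property
    def dummy_endpoints(self) -> list[str]:
        return [e for e in ("A", "B") if self.hybrids[e].dummy_atoms()]


_MOLS = {
    "MET": methane, "ETH": lambda: _alkane(2), "PRP": lambda: _alkane(3, h32_anti=True),
    "HEX": lambda: _alkane(6), "TOL": toluene, "WAT": water,
    "MEOH": methanol, "POL": propanol, "PHE": phenol,
    "DIM": dimethyl_ether, "PYR": pyridine, "CYC": cyclohexadienone,
    "AMM": ammonia, "MTA": methylamine, "ACE": acetone, "PEOL": propenol,
}

# atom maps (state A name, state B name) per pair
_MAPS: dict[str, list[tuple[str, str]]] = {
    "HEX2PRP": [("C1", "C1"), ("C2", "C2"), ("C3", "C3"),
                ("H11", "H11"), ("H12", "H12"), ("H13", "H13"),
                ("H21", "H21"), ("H22", "H22"),
                ("H31", "H31"), ("H32", "H33"), ("C4", "H32")],
    "TOL2MET": [("C", "C"), ("H1", "H1"), ("H2", "H2"), ("H3", "H3"),
                ("C1", "H4")],
    "ETH2MEOH": [("C1", "C"), ("H11", "H1"), ("H12", "H2"), ("H13", "H3"),
                 ("C2", "O"), ("H21", "HO")],
    "MET2WAT": [("C", "O"), ("H1", "H1"), ("H2", "H2")],
    "TOL2PYR": [("C1", "N"), ("C2", "C1"), ("C3", "C2"), ("C4", "C3"),
                ("C5", "C4"), ("C6", "C5"),
                ("HR2", "H1"), ("HR3", "H2"), ("HR4", "H3"),
                ("HR5", "H4"), ("HR6", "H5")],
    "HEX2POL": [("C1", "C1"), ("C2", "C2"), ("C3", "C3"),
                ("H11", "H11"), ("H12", "H12"), ("H13", "H13"),
                ("H21", "H21"), ("H22", "H22"),
                ("H31", "H31"), ("H32", "H32"),
                ("C4", "O"), ("H41", "HO")],
    "PRP2DIM": [("C1", "C1"), ("C2", "O"), ("C3", "C2"),
                ("H11", "H11"), ("H12", "H12"), ("H13", "H13"),
                ("H31", "H21"), ("H32", "H22"), ("H33", "H23")],
    "PHE2CYC": [("C1", "C1"), ("C2", "C2"), ("C3", "C3"), ("C4", "C4"),
                ("C5", "C5"), ("C6", "C6"), ("O", "O"),
                ("H2", "H2"), ("H3", "H3"), ("H4", "H4"),
                ("H5", "H5"), ("H6", "H6")],
    "ETH2MTA": [("C1", "C"), ("H11", "HC1"), ("H12", "HC2"), ("H13", "HC3"),
                ("C2", "N"), ("H21", "HN1"), ("H22", "HN2")],
    "MET2AMM": [("C", "N"), ("H1", "H1"), ("H2", "H2"), ("H3", "H3")],
    "ETH2AMM": [("C1", "N"), ("H11", "H1"), ("H12", "H2"), ("H13", "H3")],
    "ACE2PEOL": [("C1", "C1"), ("C2", "C2"), ("C3", "C3"), ("O", "O"),
                 ("H11", "H11"), ("H12", "H12"),
                 ("H31", "H31"), ("H32", "H32"), ("H33", "H33")],
}

_PAIR_STATES = {p: (p.split("2")[0], p.split("2")[1]) for p in _MAPS}
_PAIR_STATES["ACE2PEOL-DT"] = ("ACE", "PEOL")

# per-label curation settings and printed expectations (n_dum, n_mod)
_LABELS: dict[str, dict] = {
    "HEX2PRP-1": dict(pair="HEX2PRP", n_dum=9, n_mod=0,
                      opts_b=dict(keep_atom={"H32": "C2"})),
    "HEX2PRP-2": dict(pair="HEX2PRP", n_dum=9, n_mod=0,
                      opts_b=dict(mode="naive")),
    "TOL2MET": dict(pair="TOL2MET", n_dum=10, n_mod=0,
                    opts_b=dict(keep_atom={"H4": "H1"})),
    "ETH2MEOH": dict(pair="ETH2MEOH", n_dum=2, n_mod=4, opts_b=dict()),
    "MET2WAT": dict(pair="MET2WAT", n_dum=2, n_mod=4, opts_b=dict()),
    "TOL2PYR-1": dict(pair="TOL2PYR", n_dum=4, n_mod=2,
                      opts_b=dict(keep_atom={"N": "C1"})),
    "TOL2PYR-2": dict(pair="TOL2PYR", n_dum=4, n_mod=1,
                      opts_b=dict(dual_anchor="dihedral", keep_atom={"N": "C1"})),
    "HEX2POL-1": dict(pair="HEX2POL", n_dum=8, n_mod=4,
                      opts_b=dict(keep_atom={"O": "C3"})),
    "HEX2POL-2": dict(pair="HEX2POL", n_dum=8, n_mod=0,
                      opts_b=dict(mode="naive")),
    "PRP2DIM-1": dict(pair="PRP2DIM", n_dum=2, n_mod=4, opts_b=dict()),
    "PRP2DIM-2": dict(pair="PRP2DIM", n_dum=2, n_mod=0,
                      opts_b=dict(dual_anchor="dihedral", harden_dihedral=False)),
    "PRP2DIM-3": dict(pair="PRP2DIM", n_dum=2, n_mod=0,
                      opts_b=dict(dual_anchor="dihedral", harden_dihedral=False,
                                  keep_dxd_angle=True)),
    "PHE2CYC": dict(pair="PHE2CYC", n_dum=1, n_mod=2,
                    opts_a=dict(delete_neighbor={"C6": "H6"}),
                    opts_b=dict(keep_atom={"O": "C2"})),
    "ETH2MTA-1": dict(pair="ETH2MTA", n_dum=1, n_mod=3, opts_b=dict()),
    "ETH2MTA-2": dict(pair="ETH2MTA", n_dum=1, n_mod=3,
                      opts_b=dict(soft_angle_k=50.0)),
    "MET2AMM-1": dict(pair="MET2AMM", n_dum=1, n_mod=3, opts_b=dict()),
    "MET2AMM-2": dict(pair="MET2AMM", n_dum=1, n_mod=3,
                      opts_b=dict(soft_angle_k=50.0)),
    "MET2AMM-3": dict(pair="MET2AMM", n_dum=1, n_mod=0,
                      opts_b=dict(mode="naive")),
    "ETH2AMM-1": dict(pair="ETH2AMM", n_dum=4, n_mod=3, opts_b=dict()),
    "ETH2AMM-2": dict(pair="ETH2AMM", n_dum=4, n_mod=3,
                      opts_b=dict(soft_angle_k=50.0)),
    "ETH2AMM-3": dict(pair="ETH2AMM", n_dum=4, n_mod=0,
                      opts_b=dict(mode="naive")),
    "ACE2PEOL-1": dict(pair="ACE2PEOL", n_dum=1, n_mod=2,
                       opts_a=dict(keep_atom={"O": "C3"}),
                       opts_b=dict(delete_neighbor={"C1": "H12"})),
    "ACE2PEOL-2": dict(pair="ACE2PEOL-DT", n_dum=6, n_mod=6, dual_topology=True,
                       opts_a=dict(keep_atom={"C3": "H4"}),
                       opts_b=dict(keep_atom={"C3": "H4"})),
    "ACE2PEOL-3": dict(pair="ACE2PEOL-DT", n_dum=6, n_mod=0, dual_topology=True,
                       opts_a=dict(mode="naive"), opts_b=dict(mode="naive")),
}

# the quick-timestep repeat of MET2WAT uses the identical topology setup and
# edit plan; accept it as an alias rather than a distinct fixture
_ALIASES = {"MET2WAT-qfs": "MET2WAT"}

FIXTURE_LABELS = list(_LABELS)


def _ace2peol_dual_hybrids() -> tuple[Topology, Topology]:
    """The acetone / 2-propenol dual-topology hybrid of both endpoints.

    One 16-atom molecule: shared methyl (C3, H4-H6), acetone branch
    (C2, O, C1, H11-H13) and 2-propenol branch (C2p, Op, HOp, C1p,
    H11p, H12p).  The two branches share no bonded terms; at each endpoint
    the respective other branch is the dummy group.
    """
    m = _Mol()
    m.add("C3", "C")
    m.add("C2", "C", ("C3",), _B["CC"])
    m.add("H4", "H", ("C3", "C2"), _B["CH"], TD)
    m.add("H5", "H", ("C3", "C2", "H4"), _B["CH"], TD, 120.0)
    m.add("H6", "H", ("C3", "C2", "H4"), _B["CH"], TD, -120.0)
    # acetone branch
    m.add("O", "O", ("C2", "C3", "H4"), _B["CO"], 120.0, 30.0)
    m.add("C1", "C", ("C2", "C3", "O"), _B["CC"], 120.0, 180.0)
    for h, phi in (("H11", 0.0), ("H12", 120.0), ("H13", -120.0)):
        m.add(h, "H", ("C1", "C2", "O"), _B["CH"], TD, phi)
    # 2-propenol branch, anchored at C3 next to (on top of) the acetone branch
    m.add("C2p", "C", ("C3", "C2", "H4"), _B["CC"], 25.0, 0.0)
    m.add("Op", "O", ("C2p", "C3", "H4"), _B["CO"], 120.0, 30.0)
    m.add("C1p", "C", ("C2p", "C3", "Op"), _B["CC"], 120.0, 180.0)
    m.add("HOp", "H", ("Op", "C2p", "C1p"), _B["OH"], TD, 180.0)
    m.add("H11p", "H", ("C1p", "C2p", "Op"), _B["CH"], 120.0, 0.0)
    m.add("H12p", "H", ("C1p", "C2p", "Op"), _B["CH"], 120.0, 180.0)

    top = m.topology(minimize_geometry=False)
    branch_a = {"C2", "O", "C1", "H11", "H12", "H13"}
    branch_e = {"C2p", "Op", "HOp", "C1p", "H11p", "H12p"}

    def strip_interbranch(t: Topology) -> None:
        for name in ("bond_terms", "angle_terms", "urey_bradley_terms",
                     "dihedral_terms", "improper_terms"):
            kept = [term for term in getattr(t, name)
                    if not (set(term.atoms) & branch_a and set(term.atoms) & branch_e)]
            setattr(t, name, kept)

    strip_interbranch(top)

    def endpoint_hybrid(dummy_branch: set[str]) -> Topology:
        hyb = top.copy()
        for a in dummy_branch:
            hyb.atoms[a].is_dummy = True
        # minimize the physical subsystem, then relax the dummy branch onto it
        from .checks import strip_dummies
        from .mm import EnergyModel, minimize

        phys, x_phys = strip_dummies(hyb, hyb.coords_array())
        x_min, _, _ = minimize(EnergyModel(phys), x_phys)
        coords = {a: xyz for a, xyz in zip(phys.atoms, x_min)}
        for a, atom in hyb.atoms.items():
            if a in coords:
                atom.coords = tuple(coords[a])
        _relax_dummies(hyb)
        return hyb

    return endpoint_hybrid(branch_e), endpoint_hybrid(branch_a)


def build_fixture(label: str) -> FixturePair:
    """Deterministically construct one of the 24 transformation fixtures."""
    label = _ALIASES.get(label, label)
    if label not in _LABELS:
        raise KeyError(f"unknown fixture label {label!r}; see FIXTURE_LABELS")
    spec = _LABELS[label]
    pair = spec["pair"]
    dual = spec.get("dual_topology", False)
    st_a, st_b = _PAIR_STATES[pair]
    top_a = _MOLS[st_a]().topology()
    top_b = _MOLS[st_b]().topology()

    if dual:
        hyb_a, hyb_b = _ace2peol_dual_hybrids()
        amap = None
    else:
        amap = AtomMap(_MAPS[pair])
        hyb_a = _hybrid_with_coords(top_a, top_b, amap, "A")
        hyb_b = _hybrid_with_coords(top_a, top_b, amap, "B")

    options = {
        "A": CurationOptions(**spec.get("opts_a", {})),
        "B": CurationOptions(**spec.get("opts_b", {})),
    }
    n_by_ep = {"A": len(hyb_a.dummy_atoms()), "B": len(hyb_b.dummy_atoms())}
    return FixturePair(
        label=label, pair=pair, top_a=top_a, top_b=top_b, amap=amap,
        hybrids={"A": hyb_a, "B": hyb_b}, options=options,
        expected_n_dum=spec["n_dum"], expected_n_mod=spec["n_mod"],
        n_dum_by_endpoint=n_by_ep, dual_topology=dual,
    )


def curate_fixture(fp: FixturePair, endpoint: str):
    """Run partition -> classify -> curate for one endpoint of a fixture.

    Returns ``(hybrid, partition, junctions, plan)``.
    """
    hybrid = fp.hybrids[endpoint]
    partition = partition_dummies(hybrid, endpoint=endpoint)
    dt = {"C3"} if fp.dual_topology else set()
    junctions = classify_junctions(
        hybrid, partition,
        reference_coords=hybrid.coords_array(),
        dual_topology_bridges=dt,
    )
    plan = curate(hybrid, partition, junctions, fp.options[endpoint])
    return hybrid, partition, junctions, plan


# --------------------------------------------------------------------------
# published edit plans (test oracles for the four worked examples)
# --------------------------------------------------------------------------


def expected_plan(label: str) -> dict[str, dict[str, set]]:
    """Literal Deleted/Modified term sets of the four published worked
    examples, translated into fixture atom names; keyed by endpoint."""
    D = lambda *a: ("dihedral", a)
    A = lambda *a: ("angle", a)
    plans = {
        "HEX2PRP-1": {
            "B": {
                "deleted": {D(d, "H32", "C3", p)
                            for d in ("D_C5", "D_H41", "D_H42")
                            for p in ("H31", "H33")},
                "modified": set(),
            }
        },
        "TOL2PYR-1": {
            "B": {
                "deleted": {
                    D("D_C", "N", "C1", "C2"), D("D_C", "N", "C1", "H1"),
                    D("D_C", "N", "C5", "H5"), D("D_C", "N", "C5", "C4"),
                    D("D_H1", "D_C", "N", "C5"), D("D_H2", "D_C", "N", "C5"),
                    D("D_H3", "D_C", "N", "C5"),
                },
                "modified": {A("D_C", "N", "C1"), A("D_C", "N", "C5")},
            }
        },
        "TOL2PYR-2": {
            "B": {
                "deleted": {
                    A("D_C", "N", "C5"),
                    D("D_C", "N", "C1", "H1"),
                    D("D_C", "N", "C5", "H5"), D("D_C", "N", "C5", "C4"),
                    D("D_H1", "D_C", "N", "C5"), D("D_H2", "D_C", "N", "C5"),
                    D("D_H3", "D_C", "N", "C5"),
                },
                "modified": {D("D_C", "N", "C1", "C2")},
            }
        },
        "ACE2PEOL-1": {
            "A": {
                "deleted": {D("D_H", "O", "C2", "C1")},
                "modified": set(),
            },
            "B": {
                "deleted": {
                    A("D_H13", "C1", "H12"),
                    D("D_H13", "C1", "C2", "C3"), D("D_H13", "C1", "C2", "O"),
                },
                "modified": {A("D_H13", "C1", "H11"), A("D_H13", "C1", "C2")},
            },
        },
    }
    if label not in plans:
        raise KeyError(f"no published worked-example plan for {label!r}")
    from .molgraph import AngleTerm, DihedralTerm

    def canon(kind, atoms):
        if kind == "angle":
            return kind, AngleTerm(atoms, 1, 0).atoms
        return kind, DihedralTerm(atoms, 1, 1, 0).atoms

    out = {}
    for ep, d in plans[label].items():
        out[ep] = {
            "deleted": {canon(k, a) for k, a in d["deleted"]},
            "modified": {canon(k, a) for k, a in d["modified"]},
        }
    return out
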