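"""Symbolic detection of dummy-physical couplings that break separability.

Dummy-atom contributions cancel from double free energy differences only if
the partition function factorizes into a physical part and a dummy part.
Factorization requires each dummy atom near the physical system to be held by
exactly three nonredundant bonded terms; redundant terms are harmless when
they involve only dummy coordinates, but *redundant terms that couple dummy
and physical internal coordinates* destroy separability.  The detectors in
this module enumerate exactly those situations from the term lists -- no
sampling, no numerics -- and report which physical degrees of freedom are
implicated:

``six_angle``
    More angle terms around one center than the 2m - 3 nonredundant ones,
    with both purely-physical and dummy-containing angles in the coupled set.
``single_anchored_dihedral`` / ``dual_anchored_dihedral``
    Two retained dummy-containing dihedrals sharing three atoms (a common
    anchor bond) or only the central bond; the difference of the two dihedral
    angles is a function of valence angles, which couples them to the
    physical angles among those.
``urey_bradley``
    A 1-3 distance term on an angle with exactly one dummy member closes a
    triangle whose physical edge becomes constrained.
``coupled_three_angles``
    A dummy anchored by one bond plus two angles at a branched center
    constrains the physical angle between the two flanks; setting both dummy
    equilibrium angles to 90 degrees removes the effect for all practical
    purposes (severity ``mitigated``).
``redundant_count``
    Mixed dummy/physical improper dihedrals (reported, and deleted by the
    best-practice curation, which never uses impropers to attach dummies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .molgraph import Topology, term_label
from .alchemy import DummyPartition

__all__ = [
    "CouplingFinding",
    "detect_six_angle",
    "detect_dihedral_couplings",
    "detect_urey_bradley",
    "detect_coupled_three_angles",
    "detect_redundant_impropers",
    "all_findings",
    "separability_verdict",
]

BREAKS = "breaks_separability"
MITIGATED = "mitigated"


@dataclass(frozen=True)
class CouplingFinding:
    kind: str
    terms: tuple[tuple[str, ...], ...]        # offending terms (canonical tuples)
    physical_dofs: tuple[tuple[str, ...], ...]  # implicated physical coordinates
    severity: str = BREAKS

    def to_json(self) -> dict:
        return {
            "kind": self.kind,
            "terms": ["-".join(t) for t in self.terms],
            "physical_dofs": ["-".join(t) for t in self.physical_dofs],
            "severity": self.severity,
        }


def _is_physical(atoms, dummies) -> bool:
    return not any(a in dummies for a in atoms)


def _has_dummy(atoms, dummies) -> bool:
    return any(a in dummies for a in atoms)


# --------------------------------------------------------------------------


def detect_six_angle(topology: Topology, dummy_set: set[str]) -> list[CouplingFinding]:
    """Over-determined angle sets around one center that mix dummy and
    physical angles.

    Around a center with m neighbors only 2m - 3 angles are nonredundant.
    Exceeding that count creates algebraic constraints among all angles at
    the center; the constraint is harmless if the redundancy involves only
    dummy-containing angles (it factorizes), and breaks separability when
    purely-physical angles are drawn in.
    """
    g = topology.graph()
    findings = []
    by_center: dict[str, list] = {}
    for t in topology.angle_terms:
        by_center.setdefault(t.center, []).append(t)
    for c in sorted(by_center):
        angles = by_center[c]
        m = g.degree(c)
        nonredundant = 2 * m - 3
        if len(angles) <= nonredundant:
            continue
        dummy_angles = [t for t in angles if _has_dummy(t.atoms, dummy_set)]
        phys_angles = [t for t in angles if _is_physical(t.atoms, dummy_set)]
        if dummy_angles and phys_angles:
            findings.append(
                CouplingFinding(
                    kind="six_angle",
                    terms=tuple(t.atoms for t in dummy_angles),
                    physical_dofs=tuple(t.atoms for t in phys_angles),
                )
            )
    return findings


def detect_dihedral_couplings(topology: Topology, dummy_set: set[str]) -> list[CouplingFinding]:
    """Pairs of retained dummy-containing dihedrals whose difference is a
    function of purely-physical valence angles.

    Two dihedrals over the same central bond are related through the angles
    of the projections of their outer bonds onto the plane perpendicular to
    that bond.  If they share an outer bond as well (three common atoms) the
    coupling is *single-anchored*; with distinct outer atoms on both sides it
    is *dual-anchored*.  Either way, the implicated valence angles sit at the
    ends of the central bond; a finding is emitted only when at least one of
    them is purely physical (dummy-internal redundancy factorizes).
    """
    findings = []
    dummy_dihedrals = [t for t in topology.dihedral_terms if _has_dummy(t.atoms, dummy_set)]
    by_bond: dict[tuple, list] = {}
    for t in dummy_dihedrals:
        by_bond.setdefault(t.central_bond, []).append(t)
    angle_set = {t.atoms for t in topology.angle_terms}

    def orient(t, bond):
        # return (outer_at_bond0, outer_at_bond1) for central bond (b0, b1)
        a, b, c, d = t.atoms
        return (a, d) if (b, c) == bond else (d, a)

    for bond in sorted(by_bond):
        group = by_bond[bond]
        if len(group) < 2:
            continue
        b0, b1 = bond
        for t1, t2 in combinations(sorted(group, key=lambda t: t.atoms), 2):
            o1 = orient(t1, bond)
            o2 = orient(t2, bond)
            shared0 = o1[0] == o2[0]
            shared1 = o1[1] == o2[1]
            if shared0 and shared1:
                continue  # identical atom tuple cannot occur (canonical storage)
            # implicated angles: between differing outer bonds and between each
            # differing outer bond and the central bond, at each end
            implicated: list[tuple[str, ...]] = []
            for end, (x1, x2), other in (((b0), (o1[0], o2[0]), b1), ((b1), (o1[1], o2[1]), b0)):
                if x1 == x2:
                    continue
                implicated.append(tuple(sorted((x1, x2))[:1] + [end] + sorted((x1, x2))[1:]))
                implicated.append((min(x1, other), end, max(x1, other)))
                implicated.append((min(x2, other), end, max(x2, other)))
            phys = [a for a in implicated if _is_physical(a, dummy_set)]
            if not phys:
                continue  # relation couples only dummy coordinates: harmless
            # the constraint equation closes over bonded terms only if every
            # implicated dummy-containing angle is itself a retained term;
            # otherwise that projection angle is a free dummy coordinate and
            # no dependence on the physical angles arises (e.g. two dihedral
            # anchors of different dummy groups with the D-X-D angle deleted)
            dummy_implicated = [a for a in implicated if not _is_physical(a, dummy_set)]
            if any(a not in angle_set for a in dummy_implicated):
                continue
            kind = (
                "single_anchored_dihedral" if (shared0 or shared1)
                else "dual_anchored_dihedral"
            )
            findings.append(
                CouplingFinding(
                    kind=kind,
                    terms=(t1.atoms, t2.atoms),
                    physical_dofs=tuple(dict.fromkeys(phys)),
                )
            )
    return findings


def detect_urey_bradley(topology: Topology, dummy_set: set[str]) -> list[CouplingFinding]:
    """Urey-Bradley terms on angles with exactly one dummy member.

    The 1-3 distance term closes a triangle over the angle's three atoms;
    with one dummy member, the law of cosines ties the dummy coordinates to
    the purely-physical edge, which breaks separability.  Terms with two or
    more dummy members involve no physical edge and are harmless.
    """
    findings = []
    angle_by_outer = {frozenset(t.outer): t for t in topology.angle_terms}
    for ub in topology.urey_bradley_terms:
        parent = angle_by_outer.get(frozenset(ub.atoms))
        members = parent.atoms if parent else ub.atoms
        n_dum = sum(1 for a in members if a in dummy_set)
        if n_dum == 1:
            phys = tuple(a for a in members if a not in dummy_set)
            findings.append(
                CouplingFinding(
                    kind="urey_bradley",
                    terms=(ub.atoms,),
                    physical_dofs=(phys,),
                )
            )
    return findings


def detect_coupled_three_angles(topology: Topology, dummy_set: set[str],
                                right_angle_tol: float = 1e-6) -> list[CouplingFinding]:
    """Bond-plus-two-angles anchoring at a branched center.

    Even with exactly three nonredundant terms, a dummy held by one bond and
    two angles to a center with two physical flanks constrains the physical
    flank angle.  When both dummy equilibrium angles are 90 degrees the
    constraint decouples for all practical purposes (severity ``mitigated``).
    A dummy whose anchoring involves a dihedral is not of this pattern.
    """
    findings = []
    g = topology.graph()
    angle_set = {t.atoms: t for t in topology.angle_terms}
    for d in sorted(dummy_set):
        # a dummy that is itself anchored by a dihedral into the physical
        # system (terminal position, other three atoms physical) is of the
        # bond-angle-dihedral pattern instead; this rule does not apply
        anchored_by_dihedral = any(
            (t.atoms[0] == d and _is_physical(t.atoms[1:], dummy_set))
            or (t.atoms[3] == d and _is_physical(t.atoms[:3], dummy_set))
            for t in topology.dihedral_terms
        )
        if anchored_by_dihedral:
            continue
        # angles d-X-p with p physical, grouped by center X
        by_center: dict[str, list] = {}
        for t in topology.angle_terms:
            if d in t.outer:
                other = t.outer[0] if t.outer[1] == d else t.outer[1]
                if other not in dummy_set:
                    by_center.setdefault(t.center, []).append((t, other))
        for x, pairs in sorted(by_center.items()):
            if len(pairs) != 2 or x in dummy_set:
                continue
            if not g.has_edge(d, x):
                continue  # anchored elsewhere; not the bond+two-angles pattern
            (t1, p1), (t2, p2) = pairs
            phys_angle = tuple(sorted((p1, p2))[:1] + [x] + sorted((p1, p2))[1:])
            mitigated = (
                abs(t1.theta0 - 90.0) <= right_angle_tol
                and abs(t2.theta0 - 90.0) <= right_angle_tol
            )
            findings.append(
                CouplingFinding(
                    kind="coupled_three_angles",
                    terms=(t1.atoms, t2.atoms),
                    physical_dofs=(phys_angle,),
                    severity=MITIGATED if mitigated else BREAKS,
                )
            )
    return findings


def detect_redundant_impropers(topology: Topology, dummy_set: set[str]) -> list[CouplingFinding]:
    """Improper dihedrals mixing dummy and physical atoms.

    Impropers redefine orientation on top of the regular anchoring and are
    not recommended as a means of attaching dummy atoms; mixed ones are
    reported as pure over-determination and deleted by default curation.
    """
    findings = []
    for t in topology.improper_terms:
        n_dum = sum(1 for a in t.atoms if a in dummy_set)
        if 0 < n_dum < 4:
            findings.append(
                CouplingFinding(
                    kind="redundant_count",
                    terms=(t.atoms,),
                    physical_dofs=tuple(
                        (a,) for a in t.atoms if a not in dummy_set
                    ),
                )
            )
    return findings


# --------------------------------------------------------------------------


def all_findings(topology: Topology, dummy_set: set[str]) -> list[CouplingFinding]:
    return (
        detect_six_angle(topology, dummy_set)
        + detect_dihedral_couplings(topology, dummy_set)
        + detect_urey_bradley(topology, dummy_set)
        + detect_coupled_three_angles(topology, dummy_set)
        + detect_redundant_impropers(topology, dummy_set)
    )


def separability_verdict(topology: Topology, partition: DummyPartition):
    """Pure function of the term lists: ``separable`` with zero findings,
    ``separable_mitigated`` if only mitigated findings remain, ``coupled``
    otherwise.  Returns ``(verdict, findings)``."""
    findings = all_findings(topology, partition.dummy_atoms)
    if not findings:
        return "separable", findings
    if all(f.severity == MITIGATED for f in findings):
        return "separable_mitigated", findings
    return "coupled", findings
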