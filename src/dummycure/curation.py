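"""Best-practice (and naive) bonded-term edit plans for dummy junctions.

Given a hybrid topology, its dummy partition and the classified junctions,
:func:`curate` produces an :class:`EditPlan`: the set of term deletions and
parameter modifications that makes the dummy contribution to the partition
function factor out (or, where that is impossible, minimizes the damage)
while keeping every dummy atom and group in a well-defined position and
orientation.  The rules per junction kind:

terminal
    Keep all angles; delete Urey-Bradley terms with exactly one dummy
    member; of the dihedrals reaching into the dummy groups keep only those
    terminating at ONE chosen physical atom two bonds from the bridge atom X.
dual, single branch
    Either anchor the dummy bridge atom by the bridge bond plus angles to
    both physical neighbors of X, equilibria set to 90 deg with a hard force
    constant (``two_angles``), deleting every dihedral that anchors it into
    the physical side; or keep one bond / one angle / one dihedral
    (``dihedral``), deleting the competing angle, with the anchor dihedral
    made single-welled (periodicity 1, raised force constant).  Deeper dummy
    dihedrals are pruned so that all of them terminate at one physical atom.
dual, two branches
    Delete every term containing dummies from both groups (exception: the
    D-X-D angle may be kept when both bridges are dihedral-anchored), then
    treat each branch independently as above.
triple, planar
    Disconnect one physical neighbor from the dummies entirely; anchor by
    the bridge bond plus two 90-degree hard angles to the remaining two.
triple, nonplanar
    Keep all three X-centered dummy angles but make them soft (k = 3.55
    kcal/(mol rad^2)) with equilibrium values calibrated so the physical
    minimum is untouched; prune crossing dihedrals as for dual junctions.
    Separability is knowingly sacrificed here to prevent flapping.
dual topology / higher junctions
    After verifying the two branches share no terms, each endpoint reduces
    to a nonplanar triple junction over the shared core, with crossing
    dihedrals kept to exactly one shared-core atom.
naive mode
    Keep every bonded term with the physical-endpoint parameters; only
    Urey-Bradley terms with exactly one dummy member are deleted.

Plans never touch a term composed solely of physical atoms, and applying a
plan then re-curating yields an empty plan (idempotence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alchemy import DummyPartition, Junction
from .molgraph import (
    AngleTerm,
    BondTerm,
    DihedralTerm,
    ImproperTerm,
    Topology,
    TopologyError,
    UreyBradleyTerm,
    term_kind,
    term_label,
)

__all__ = [
    "AnchorScheme",
    "CurationOptions",
    "EditPlan",
    "curate",
    "apply_plan",
    "count_modifications",
    "calibrate_equilibrium_angles",
]

HARD_ANGLE_K = 100.0     # kcal/(mol rad^2), anchor angles at 90 deg
HARD_ANGLE_THETA0 = 90.0
HARD_DIHEDRAL_K = 100.0  # kcal/mol, periodicity-1 anchor dihedral
SOFT_ANGLE_K = 3.55      # kcal/(mol rad^2), nonplanar-triple soft angles
PROBE_K = 0.05           # kcal/(mol rad^2), calibration probe


@dataclass
class AnchorScheme:
    """How one bridge-adjacent dummy atom is positioned."""

    dummy_atom: str
    variant: str  # bond_angle_dihedral | bond_two_angles | bond_three_angles | intra_group
    anchor_terms: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)


@dataclass
class Modification:
    kind: str
    atoms: tuple[str, ...]
    old_params: tuple
    new_params: tuple
    reason: str

    def to_json(self) -> dict:
        return {
            "kind": self.kind,
            "term": "-".join(self.atoms),
            "old_params": list(self.old_params),
            "new_params": list(self.new_params),
            "reason": self.reason,
        }


@dataclass
class EditPlan:
    endpoint: str
    mode: str
    deletions: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    modifications: list[Modification] = field(default_factory=list)
    anchor_schemes: list[AnchorScheme] = field(default_factory=list)

    def deletion_labels(self) -> set[str]:
        return {"-".join(a) for _, a in self.deletions}

    def modification_labels(self) -> set[str]:
        return {"-".join(m.atoms) for m in self.modifications}

    def to_json(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "mode": self.mode,
            "deletions": [{"kind": k, "term": "-".join(a)} for k, a in self.deletions],
            "modifications": [m.to_json() for m in self.modifications],
            "anchor_schemes": [
                {
                    "dummy_atom": s.dummy_atom,
                    "variant": s.variant,
                    "anchor_terms": [{"kind": k, "term": "-".join(a)} for k, a in s.anchor_terms],
                }
                for s in self.anchor_schemes
            ],
        }

    def to_markdown(self) -> str:
        lines = [f"### Edit plan ({self.mode}, endpoint {self.endpoint})", "", "| Deleted | Modified |", "|---|---|"]
        dels = sorted(self.deletion_labels())
        mods = sorted(
            f"{'-'.join(m.atoms)} ({m.reason})" for m in self.modifications
        )
        for i in range(max(len(dels), len(mods), 1)):
            d = dels[i] if i < len(dels) else ""
            m = mods[i] if i < len(mods) else ""
            lines.append(f"| {d or ('None' if i == 0 and not dels else '')} "
                         f"| {m or ('None' if i == 0 and not mods else '')} |")
        return "\n".join(lines)


@dataclass
class CurationOptions:
    """Knobs of the curation engine; defaults are the best-practice values."""

    mode: str = "best_practice"          # or "naive"
    dual_anchor: str = "two_angles"      # or "dihedral"
    keep_atom: dict[str, str] = field(default_factory=dict)      # bridge X -> kept physical atom
    delete_neighbor: dict[str, str] = field(default_factory=dict)  # planar triple: X -> disconnected neighbor
    harden_dihedral: bool = True         # periodicity-1/k=100 on the anchor dihedral
    keep_dxd_angle: bool = False         # two-branch dual with both dihedral anchors
    hard_angle_k: float = HARD_ANGLE_K
    hard_angle_theta0: float = HARD_ANGLE_THETA0
    hard_dihedral_k: float = HARD_DIHEDRAL_K
    soft_angle_k: float = SOFT_ANGLE_K
    probe_k: float = PROBE_K
    calibrate: bool = True               # nonplanar triple theta0 calibration


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------


def _one_dummy_ub_deletions(top: Topology, dummies: set[str]) -> list:
    """UB terms whose parent angle has exactly one dummy member (deleted in
    every mode, naive included)."""
    out = []
    angle_by_outer = {frozenset(t.outer): t for t in top.angle_terms}
    for ub in top.urey_bradley_terms:
        parent = angle_by_outer.get(frozenset(ub.atoms))
        members = parent.atoms if parent else ub.atoms
        if sum(1 for a in members if a in dummies) == 1:
            out.append(("ureybradley", ub.atoms))
    return out


def _subtree_size(g, root: str, blocked: str) -> int:
    """Atoms reachable from root without passing through ``blocked``."""
    seen = {blocked, root}
    stack = [root]
    n = 0
    while stack:
        for nb in g.neighbors(stack.pop()):
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
                n += 1
    return n


def _default_keep_atom(top: Topology, g, candidates: list[str], via: str) -> str:
    """Kept-physical-atom heuristic: prefer the heavy atom carrying the
    longest physical chain (most atoms behind it), then lexicographic."""
    def key(p):
        heavy = top.atoms[p].element != "H"
        return (heavy, _subtree_size(g, p, via), [-ord(c) for c in p])
    return max(sorted(candidates), key=key)


def _crossing_ends(t: DihedralTerm, dummies: set[str]) -> tuple[str, str] | None:
    """(dummy_end, physical_end) for a dihedral crossing one bridge bond.

    A crossing dihedral is a 4-path with a contiguous dummy prefix and a
    physical suffix (in one of the two traversal directions); returns None
    for purely-physical, purely-dummy or doubly-crossing paths.
    """
    for seq in (t.atoms, t.atoms[::-1]):
        fl = [a in dummies for a in seq]
        if fl[0] and not fl[-1]:
            i = fl.index(False)
            if not any(fl[i:]):
                return seq[0], seq[-1]
    return None


# --------------------------------------------------------------------------
# calibration of soft-angle equilibrium values
# --------------------------------------------------------------------------


def calibrate_equilibrium_angles(topology: Topology,
                                 soft_angle_terms: list[tuple[str, ...]],
                                 probe_k: float = PROBE_K,
                                 coords: np.ndarray | None = None,
                                 max_cycles: int = 10,
                                 tol: float = 1e-7) -> dict[tuple[str, ...], float]:
    """Equilibrium values for soft anchor angles that leave the physical
    minimum untouched.

    The hybrid is minimized with a tiny probe force constant on the listed
    angles, the relaxed angle values are read off and substituted as the new
    equilibria, and the cycle is repeated to its fixed point.  At the fixed
    point the listed terms exert exactly zero force at the joint minimum, so
    the physical subsystem sits at its own unperturbed minimum.
    """
    from .mm import EnergyModel, measure_angle, minimize

    if not soft_angle_terms:
        return {}
    wanted = {AngleTerm(t, 1.0, 0.0).atoms for t in soft_angle_terms}
    work = topology.copy()
    if coords is None:
        coords = work.coords_array()
    coords = np.asarray(coords, float).reshape(-1, 3)
    ids = list(work.atoms)
    pos = {a: i for i, a in enumerate(ids)}

    theta0 = {
        t.atoms: t.theta0 for t in work.angle_terms if t.atoms in wanted
    }
    if set(theta0) != wanted:
        missing = wanted - set(theta0)
        raise TopologyError(f"soft angle terms not present in topology: {sorted(missing)}")

    x = coords
    for _ in range(max_cycles):
        work.angle_terms = [
            replace(t, k=probe_k, theta0=theta0[t.atoms]) if t.atoms in wanted else t
            for t in work.angle_terms
        ]
        model = EnergyModel(work)
        x, _, converged = minimize(model, x)
        if not converged:
            raise TopologyError("calibration minimization did not converge")
        new = {
            t: measure_angle(x, pos[t[0]], pos[t[1]], pos[t[2]]) for t in wanted
        }
        delta = max(abs(new[t] - theta0[t]) for t in wanted)
        theta0 = new
        if delta < tol:
            break
    return dict(sorted(theta0.items()))


# --------------------------------------------------------------------------
# the curation engine
# --------------------------------------------------------------------------


def curate(topology: Topology, partition: DummyPartition,
           junctions: list[Junction],
           options: CurationOptions | None = None) -> EditPlan:
    """Generate the edit plan for one endpoint's hybrid topology."""
    opts = options or CurationOptions()
    dummies = partition.dummy_atoms
    g = topology.graph()
    plan = EditPlan(endpoint=partition.endpoint, mode=opts.mode)
    deletions: list[tuple[str, tuple[str, ...]]] = []
    mods: list[Modification] = []

    deletions.extend(_one_dummy_ub_deletions(topology, dummies))

    if opts.mode == "naive":
        plan.deletions = _dedupe(deletions)
        return plan
    if opts.mode != "best_practice":
        raise ValueError(f"unknown curation mode {opts.mode!r}")

    # best practice deletes impropers that mix dummy and physical atoms
    for t in topology.improper_terms:
        nd = sum(1 for a in t.atoms if a in dummies)
        if 0 < nd < 4:
            deletions.append(("improper", t.atoms))

    angle_index = {t.atoms: t for t in topology.angle_terms}
    dihedral_index = {t.atoms: t for t in topology.dihedral_terms}

    def modify_angle(atoms, k, theta0, reason):
        t = angle_index.get(AngleTerm(atoms, 1.0, 0.0).atoms)
        if t is None:
            raise TopologyError(f"expected angle term {'-'.join(atoms)} is missing")
        if (t.k, t.theta0) != (k, theta0):
            mods.append(Modification("angle", t.atoms, t.params, (k, theta0), reason))

    def delete_term(kind, atoms):
        deletions.append((kind, atoms))

    for junction in junctions:
        x = junction.bridge_atom
        jd = set().union(*(partition.dummy_groups[i] for i in junction.dummy_groups))
        bridge_dummies = sorted(
            d for d in jd if g.has_edge(d, x)
        )

        if junction.kind == "terminal":
            _curate_terminal(topology, g, x, jd, opts, plan, delete_term)
        elif junction.kind == "dual":
            _curate_dual(topology, g, partition, junction, opts, plan,
                         delete_term, modify_angle, angle_index, dihedral_index, mods)
        elif junction.kind == "triple" and junction.planar:
            _curate_planar_triple(topology, g, junction, jd, opts, plan,
                                  delete_term, modify_angle)
        elif junction.kind == "triple":
            _curate_nonplanar_triple(topology, g, junction, jd, opts, plan,
                                     delete_term, modify_angle, angle_index,
                                     deletions)
        elif junction.kind == "higher":
            if not junction.is_dual_topology:
                raise TopologyError(
                    f"junction at {x!r} has {len(junction.physical_neighbors)} physical "
                    "neighbors; higher junctions are only supported through the "
                    "dual-topology reduction (declare the junction dual-topology and "
                    "ensure the branches share no bonded terms)"
                )
            _curate_dual_topology(topology, g, junction, jd, opts, plan,
                                  delete_term, modify_angle, angle_index,
                                  deletions)
        else:  # pragma: no cover
            raise TopologyError(f"unhandled junction kind {junction.kind!r}")

    plan.deletions = _dedupe(deletions)
    # drop modifications of terms that the same plan deletes
    deleted = {(k, a) for k, a in plan.deletions}
    plan.modifications = [m for m in mods if (m.kind, m.atoms) not in deleted]
    _check_physical_untouched(plan, dummies)
    return plan


def _dedupe(items):
    seen, out = set(), []
    for it in items:
        if it not in seen:
            seen.add(it)
            out.append(it)
    return out


def _check_physical_untouched(plan: EditPlan, dummies: set[str]) -> None:
    for kind, atoms in plan.deletions:
        if not any(a in dummies for a in atoms):
            raise AssertionError(f"plan deletes purely-physical term {'-'.join(atoms)}")
    for m in plan.modifications:
        if not any(a in dummies for a in m.atoms):
            raise AssertionError(f"plan modifies purely-physical term {'-'.join(m.atoms)}")


# -- terminal ---------------------------------------------------------------


def _curate_terminal(top, g, x, jd, opts, plan, delete_term):
    phys_nb = [n for n in g.neighbors(x) if n not in jd and not top.atoms[n].is_dummy]
    c = phys_nb[0]
    two_away = sorted(p for p in g.neighbors(c)
                      if p != x and not top.atoms[p].is_dummy)
    if not two_away:
        kept = None  # molecule too small for crossing dihedrals
    else:
        kept = opts.keep_atom.get(x) or _default_keep_atom(top, g, two_away, c)
        if kept not in two_away:
            raise TopologyError(
                f"keep_atom {kept!r} is not a physical atom two bonds from {x!r}"
            )
    for t in top.dihedral_terms:
        ends = _crossing_ends(t, jd)
        if ends is None:
            continue
        d_end, p_end = ends
        if x in t.atoms and c in t.atoms and p_end in two_away and p_end != kept:
            delete_term("dihedral", t.atoms)
    for d in sorted(jd):
        if g.has_edge(d, x):
            plan.anchor_schemes.append(AnchorScheme(
                dummy_atom=d, variant="bond_all_angles",
                anchor_terms=[("bond", tuple(sorted((d, x))))],
            ))


# -- dual -------------------------------------------------------------------


def _curate_dual(top, g, partition, junction, opts, plan, delete_term,
                 modify_angle, angle_index, dihedral_index, mods):
    x = junction.bridge_atom
    p1, p2 = junction.physical_neighbors
    groups = [partition.dummy_groups[i] for i in junction.dummy_groups]

    if len(groups) >= 2:
        # decouple the branches: delete every term mixing two dummy groups
        def mixes(atoms):
            hit = {i for i, grp in enumerate(groups) for a in atoms if a in grp}
            return len(hit) >= 2
        for t in top.all_terms():
            if mixes(t.atoms):
                if (term_kind(t) == "angle" and opts.keep_dxd_angle
                        and opts.dual_anchor == "dihedral" and t.center == x):
                    continue  # D-X-D angle is safe with two dihedral anchors
                delete_term(term_kind(t), t.atoms)

    kept = opts.keep_atom.get(x) or _default_keep_atom(top, g, [p1, p2], x)

    for grp in groups:
        bridge = sorted(d for d in grp if g.has_edge(d, x))
        for db in bridge:
            if opts.dual_anchor == "two_angles":
                for p in (p1, p2):
                    modify_angle((db, x, p), opts.hard_angle_k, opts.hard_angle_theta0,
                                 "equilibrium angle set to 90 deg, force constant raised")
                # the two hard angles fully anchor db: delete every dihedral
                # that ties db into the physical side
                for t in top.dihedral_terms:
                    ends = _crossing_ends(t, grp)
                    if ends and ends[0] == db and x in t.atoms:
                        delete_term("dihedral", t.atoms)
                plan.anchor_schemes.append(AnchorScheme(
                    dummy_atom=db, variant="bond_two_angles",
                    anchor_terms=[("bond", tuple(sorted((db, x)))),
                                  ("angle", AngleTerm((db, x, p1), 1, 0).atoms),
                                  ("angle", AngleTerm((db, x, p2), 1, 0).atoms)],
                ))
            elif opts.dual_anchor == "dihedral":
                other = p2 if kept == p1 else p1
                a_del = AngleTerm((db, x, other), 1, 0).atoms
                if a_del in angle_index:
                    delete_term("angle", a_del)
                anchor_dih = _choose_anchor_dihedral(top, g, db, x, kept, jdummies=grp)
                for t in top.dihedral_terms:
                    ends = _crossing_ends(t, grp)
                    if ends and ends[0] == db and x in t.atoms and \
                            (anchor_dih is None or t.atoms != anchor_dih):
                        delete_term("dihedral", t.atoms)
                if anchor_dih is not None and opts.harden_dihedral:
                    t = dihedral_index[anchor_dih]
                    delta = _anchor_phase(top, anchor_dih)
                    new = (opts.hard_dihedral_k, 1, delta)
                    if t.params != new:
                        mods.append(Modification(
                            "dihedral", t.atoms, t.params, new,
                            "periodicity set to 1, force constant raised"))
                plan.anchor_schemes.append(AnchorScheme(
                    dummy_atom=db, variant="bond_angle_dihedral",
                    anchor_terms=[("bond", tuple(sorted((db, x)))),
                                  ("angle", AngleTerm((db, x, kept), 1, 0).atoms)]
                                 + ([("dihedral", anchor_dih)] if anchor_dih else []),
                ))
            else:
                raise ValueError(f"unknown dual_anchor {opts.dual_anchor!r}")
        # deeper dummies: prune crossing dihedrals to the kept physical atom
        _prune_deep_dihedrals(top, grp, set(bridge), x, kept, delete_term)


def _choose_anchor_dihedral(top, g, db, x, kept, jdummies):
    """The retained anchor dihedral db-X-kept-next; next prefers a heavy atom."""
    candidates = []
    for t in top.dihedral_terms:
        a, b, c, d = t.atoms
        path = (a, b, c, d)
        for p in (path, path[::-1]):
            if p[0] == db and p[1] == x and p[2] == kept:
                candidates.append((p[3], t.atoms))
    if not candidates:
        return None
    def key(item):
        nxt, _ = item
        return (top.atoms[nxt].element != "H", _subtree_size(g, nxt, kept),
                [-ord(ch) for ch in nxt])
    return max(sorted(candidates), key=key)[1]


def _anchor_phase(top, dih_atoms) -> float:
    """Phase delta placing the periodicity-1 minimum at the reference
    geometry's dihedral value (0 when no coordinates are available, which
    puts the minimum at 180 deg -- the trans arrangement)."""
    try:
        x = top.coords_array()
    except TopologyError:
        return 0.0
    from .mm import measure_dihedral

    ids = list(top.atoms)
    pos = {a: i for i, a in enumerate(ids)}
    phi = measure_dihedral(x, *(pos[a] for a in dih_atoms))
    delta = (phi - 180.0) % 360.0
    # snap to exact 0 for near-planar reference geometries (transplanted
    # dummy coordinates can sit a few degrees out of plane)
    return 0.0 if min(delta, 360.0 - delta) < 15.0 else round(delta, 6)


def _prune_deep_dihedrals(top, grp, bridge, x, kept, delete_term):
    """Crossing dihedrals from non-bridge dummies must all end at ``kept``."""
    for t in top.dihedral_terms:
        ends = _crossing_ends(t, grp)
        if ends is None:
            continue
        d_end, p_end = ends
        if d_end in bridge:
            continue  # bridge-atom dihedrals are handled by the anchor rules
        if x in t.atoms and p_end not in (kept, x):
            delete_term("dihedral", t.atoms)


# -- triple -----------------------------------------------------------------


def _curate_planar_triple(top, g, junction, jd, opts, plan, delete_term, modify_angle):
    x = junction.bridge_atom
    nbs = junction.physical_neighbors
    p_del = opts.delete_neighbor.get(x) or sorted(nbs)[0]
    if p_del not in nbs:
        raise TopologyError(f"delete_neighbor {p_del!r} is not bonded to {x!r}")
    keep_nbs = [p for p in nbs if p != p_del]
    # all bonded terms between the disconnected neighbor and the dummies go
    for t in top.all_terms():
        if p_del in t.atoms and any(a in jd for a in t.atoms):
            delete_term(term_kind(t), t.atoms)
    bridge = sorted(d for d in jd if g.has_edge(d, x))
    for db in bridge:
        for p in keep_nbs:
            modify_angle((db, x, p), opts.hard_angle_k, opts.hard_angle_theta0,
                         "equilibrium angle set to 90 deg, force constant raised")
        for t in top.dihedral_terms:
            ends = _crossing_ends(t, jd)
            if ends and ends[0] == db and x in t.atoms:
                delete_term("dihedral", t.atoms)
        plan.anchor_schemes.append(AnchorScheme(
            dummy_atom=db, variant="bond_two_angles",
            anchor_terms=[("bond", tuple(sorted((db, x))))] +
                         [("angle", AngleTerm((db, x, p), 1, 0).atoms) for p in keep_nbs],
        ))
    kept = opts.keep_atom.get(x)
    if kept is None and keep_nbs:
        kept = _default_keep_atom(top, g, keep_nbs, x)
    _prune_deep_dihedrals(top, jd, set(bridge), x, kept, delete_term)


def _apply_deletions_copy(top: Topology, deletions) -> Topology:
    """Copy of ``top`` with the (already planned) deletions removed."""
    out = top.copy()
    gone = set(deletions)
    out.bond_terms = [t for t in out.bond_terms if ("bond", t.atoms) not in gone]
    out.angle_terms = [t for t in out.angle_terms if ("angle", t.atoms) not in gone]
    out.urey_bradley_terms = [
        t for t in out.urey_bradley_terms if ("ureybradley", t.atoms) not in gone
    ]
    out.dihedral_terms = [
        t for t in out.dihedral_terms if ("dihedral", t.atoms) not in gone
    ]
    out.improper_terms = [
        t for t in out.improper_terms if ("improper", t.atoms) not in gone
    ]
    return out


def _curate_nonplanar_triple(top, g, junction, jd, opts, plan, delete_term,
                             modify_angle, angle_index, deletions,
                             core_neighbors=None):
    x = junction.bridge_atom
    nbs = core_neighbors if core_neighbors is not None else junction.physical_neighbors
    bridge = sorted(d for d in jd if g.has_edge(d, x))
    soft_terms = []
    for db in bridge:
        for p in nbs:
            atoms = AngleTerm((db, x, p), 1, 0).atoms
            if atoms in angle_index:
                soft_terms.append(atoms)
        for t in top.dihedral_terms:
            ends = _crossing_ends(t, jd)
            if ends and ends[0] == db and x in t.atoms:
                delete_term("dihedral", t.atoms)
        plan.anchor_schemes.append(AnchorScheme(
            dummy_atom=db, variant="bond_three_angles",
            anchor_terms=[("bond", tuple(sorted((db, x))))] +
                         [("angle", a) for a in soft_terms],
        ))
    kept = opts.keep_atom.get(x)
    if kept is None and nbs:
        kept = _default_keep_atom(top, g, list(nbs), x)
    _prune_deep_dihedrals(top, jd, set(bridge), x, kept, delete_term)
    theta0 = {a: angle_index[a].theta0 for a in soft_terms}
    if opts.calibrate and soft_terms:
        # calibrate on the junction-curated topology so the probe sees
        # exactly the terms that will survive the plan
        probe = _apply_deletions_copy(top, deletions)
        theta0 = calibrate_equilibrium_angles(probe, soft_terms, probe_k=opts.probe_k)
    for atoms in soft_terms:
        modify_angle(atoms, opts.soft_angle_k, theta0[atoms],
                     "force constant lowered, equilibrium angle calibrated")


# -- dual topology / higher -------------------------------------------------


def _curate_dual_topology(top, g, junction, jd, opts, plan, delete_term,
                          modify_angle, angle_index, deletions):
    """Higher junction handled as a dual-topology endpoint.

    The dummy group is the inactive branch.  Shared-core neighbors of X are
    the physical neighbors that actually share an angle term with the dummy
    bridge atom; the active physical branch (which shares no terms with the
    dummies -- verified here) is excluded, reducing the task to a nonplanar
    triple junction over the core.
    """
    x = junction.bridge_atom
    bridge = sorted(d for d in jd if g.has_edge(d, x))
    core, branch_roots = [], []
    for p in junction.physical_neighbors:
        has_angle = any(
            AngleTerm((db, x, p), 1, 0).atoms in angle_index for db in bridge
        )
        (core if has_angle else branch_roots).append(p)
    # the branches must never interact: no term may mix the dummy branch with
    # the physical branch subtrees
    branch_atoms: set[str] = set()
    for r in branch_roots:
        seen = {x, r}
        stack = [r]
        while stack:
            for nb in g.neighbors(stack.pop()):
                if nb not in seen and not top.atoms[nb].is_dummy:
                    seen.add(nb)
                    stack.append(nb)
        branch_atoms |= seen - {x}
    for t in top.all_terms():
        if any(a in jd for a in t.atoms) and any(a in branch_atoms for a in t.atoms):
            raise TopologyError(
                f"dual-topology branches interact through term {term_label(t)}; "
                "the two branches must share no bonded terms"
            )
    sub = replace(junction, kind="triple", planar=False)
    _curate_nonplanar_triple(top, g, sub, jd, opts, plan, delete_term,
                             modify_angle, angle_index, deletions,
                             core_neighbors=core)


# --------------------------------------------------------------------------
# plan application
# --------------------------------------------------------------------------


def apply_plan(topology: Topology, plan: EditPlan) -> Topology:
    """Apply deletions and modifications; returns a new Topology."""
    out = topology.copy()
    lists = {
        "bond": out.bond_terms,
        "angle": out.angle_terms,
        "ureybradley": out.urey_bradley_terms,
        "dihedral": out.dihedral_terms,
        "improper": out.improper_terms,
    }
    for kind, atoms in plan.deletions:
        terms = lists[kind]
        hit = [t for t in terms if t.atoms == atoms]
        if not hit:
            raise TopologyError(f"plan deletes unknown {kind} term {'-'.join(atoms)}")
        terms.remove(hit[0])
    for m in plan.modifications:
        terms = lists[m.kind]
        hit = [t for t in terms if t.atoms == m.atoms]
        if not hit:
            raise TopologyError(f"plan modifies unknown {m.kind} term {'-'.join(m.atoms)}")
        i = terms.index(hit[0])
        t = hit[0]
        if m.kind == "angle":
            terms[i] = AngleTerm(t.atoms, *m.new_params)
        elif m.kind == "bond":
            terms[i] = BondTerm(t.atoms, *m.new_params)
        elif m.kind == "ureybradley":
            terms[i] = UreyBradleyTerm(t.atoms, *m.new_params)
        elif m.kind == "dihedral":
            k, n, delta = m.new_params
            terms[i] = DihedralTerm(t.atoms, k, int(n), delta)
        elif m.kind == "improper":
            terms[i] = ImproperTerm(t.atoms, *m.new_params)
    out.validate(require_connected=True)
    return out


def count_modifications(plan: EditPlan, rel_tol: float = 1e-6) -> int:
    """Number of terms whose parameters actually changed (deletions excluded)."""
    n = 0
    for m in plan.modifications:
        same = len(m.old_params) == len(m.new_params) and all(
            abs(a - b) <= rel_tol * max(1.0, abs(a), abs(b))
            for a, b in zip(m.old_params, m.new_params)
        )
        if not same:
            n += 1
    return n
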