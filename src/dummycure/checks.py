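"""Gas-phase validation checks for curated hybrid topologies.

Check 1 (*minimum invariance*): the minimum-energy conformation of the
physical molecule must be identical whether or not the dummy atoms are
present.  Both systems are minimized; the dummies are then stripped from the
hybrid minimum and the physical model is evaluated on the remaining
coordinates *without further minimization*.  Geometry (RMSD after optimal
superposition) and energy must agree within tight tolerances.  This is a
necessary criterion, not a sufficient one: dummies can still distort
conformations away from the minimum.

Check 2 (*flapping detection*): a short Langevin run of the hybrid in the
gas phase, monitoring the anchor angles and dihedrals plus all X-centered
dummy angles.  A coordinate is flagged when its sampled distribution
occupies more than one well (modes separated by at least 60 degrees, each
with at least 5% occupancy) or, for dihedrals, when its circular variance
exceeds a threshold (a dummy dragged around by a free rotator never settles
into wells but covers the whole circle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alchemy import DummyPartition, partition_dummies
from .curation import EditPlan
from .mm import EnergyModel, Trajectory, internal_series, langevin, measure_angle, measure_dihedral, minimize
from .molgraph import Topology, TopologyError

__all__ = [
    "MinInvarianceReport",
    "FlappingReport",
    "check_min_invariance",
    "check_flapping",
    "strip_dummies",
]


# --------------------------------------------------------------------------
# check 1: minimum invariance
# --------------------------------------------------------------------------


@dataclass
class MinInvarianceReport:
    physical_min_energy: float
    stripped_energy: float
    rmsd: float
    per_coordinate: dict[str, float]
    passed: bool
    reason: str = ""

    def to_json(self) -> dict:
        return {
            "physical_min_energy": self.physical_min_energy,
            "stripped_energy": self.stripped_energy,
            "rmsd": self.rmsd,
            "per_coordinate": self.per_coordinate,
            "pass": self.passed,
            "reason": self.reason,
        }


def strip_dummies(hybrid: Topology, coords: np.ndarray) -> tuple[Topology, np.ndarray]:
    """Remove dummy atoms and every term touching them; keep physical coords."""
    dummies = hybrid.dummy_atoms()
    ids = list(hybrid.atoms)
    keep_idx = [i for i, a in enumerate(ids) if a not in dummies]
    out = Topology(scale14=hybrid.scale14)
    for a in hybrid.atoms.values():
        if a.id not in dummies:
            out.add_atom(type(a)(id=a.id, element=a.element, name=a.name,
                                 coords=a.coords, charge=a.charge,
                                 lj_params=a.lj_params))
    out.bonds = [b for b in hybrid.bonds if not (set(b) & dummies)]
    out.bond_terms = [t for t in hybrid.bond_terms if not (set(t.atoms) & dummies)]
    out.angle_terms = [t for t in hybrid.angle_terms if not (set(t.atoms) & dummies)]
    out.urey_bradley_terms = [t for t in hybrid.urey_bradley_terms if not (set(t.atoms) & dummies)]
    out.dihedral_terms = [t for t in hybrid.dihedral_terms if not (set(t.atoms) & dummies)]
    out.improper_terms = [t for t in hybrid.improper_terms if not (set(t.atoms) & dummies)]
    return out, np.asarray(coords, float).reshape(-1, 3)[keep_idx]


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial.transform import Rotation

    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a, b)
    return float(np.sqrt(np.mean(np.sum((a - rot.apply(b)) ** 2, axis=1))))


def check_min_invariance(physical: Topology, hybrid: Topology,
                         tol_geom: float = 1e-3, tol_energy: float = 1e-4,
                         ) -> MinInvarianceReport:
    """Does the hybrid's minimum reproduce the physical minimum exactly?

    ``physical`` and the hybrid's physical atoms must share atom ids.
    """
    pm = EnergyModel(physical)
    x_ref, e_ref, ok_ref = minimize(pm, physical.coords_array())
    hm = EnergyModel(hybrid)
    # start the hybrid at the physical reference minimum with the dummies
    # relaxed onto it: if the curation is correct this is already a joint
    # stationary point, and any displacement that follows is caused by the
    # dummy terms alone
    ids = list(hybrid.atoms)
    ref_pos = {a: xyz for a, xyz in zip(physical.atoms, x_ref)}
    x_start = hybrid.coords_array()
    for n, a in enumerate(ids):
        if a in ref_pos:
            x_start[n] = ref_pos[a]
    free = np.array([hybrid.atoms[a].is_dummy for a in ids])
    from .mm import minimize_subset

    x_start = minimize_subset(hm, x_start, free)
    x_hyb, _, ok_hyb = minimize(hm, x_start)
    if not (ok_ref and ok_hyb):
        return MinInvarianceReport(
            physical_min_energy=e_ref, stripped_energy=float("nan"),
            rmsd=float("nan"), per_coordinate={}, passed=False,
            reason="minimization did not converge",
        )
    stripped_top, x_strip = strip_dummies(hybrid, x_hyb)
    # evaluate with the physical model, matching atoms by id -- no reminimization
    order = [list(stripped_top.atoms).index(a) for a in physical.atoms]
    x_strip = x_strip[order]
    e_strip, _ = pm.energy(x_strip)
    rmsd = _kabsch_rmsd(x_ref, x_strip)

    per_coord: dict[str, float] = {}
    ids = list(physical.atoms)
    pos = {a: i for i, a in enumerate(ids)}
    for t in physical.angle_terms:
        i, j, k = (pos[a] for a in t.atoms)
        per_coord["-".join(t.atoms)] = abs(
            measure_angle(x_ref, i, j, k) - measure_angle(x_strip, i, j, k)
        )
    passed = rmsd <= tol_geom and abs(e_strip - e_ref) <= tol_energy
    return MinInvarianceReport(
        physical_min_energy=e_ref,
        stripped_energy=e_strip,
        rmsd=rmsd,
        per_coordinate=per_coord,
        passed=passed,
        reason="" if passed else "physical minimum differs with dummies attached",
    )


# --------------------------------------------------------------------------
# check 2: flapping detection
# --------------------------------------------------------------------------


@dataclass
class CoordinateVerdict:
    coordinate: tuple[str, ...]
    kind: str                 # angle | dihedral
    n_modes: int
    occupancies: list[float]
    mode_centers: list[float]
    circular_variance: float | None
    flagged: bool


@dataclass
class FlappingReport:
    monitored: list[CoordinateVerdict]
    flagged: list[tuple[str, ...]]
    passed: bool
    seed: int
    steps: int

    def to_json(self) -> dict:
        return {
            "pass": self.passed,
            "seed": self.seed,
            "steps": self.steps,
            "flagged": ["-".join(c) for c in self.flagged],
            "monitored": [
                {
                    "coordinate": "-".join(v.coordinate),
                    "kind": v.kind,
                    "n_modes": v.n_modes,
                    "occupancies": v.occupancies,
                    "mode_centers": v.mode_centers,
                    "circular_variance": v.circular_variance,
                    "flagged": v.flagged,
                }
                for v in self.monitored
            ],
        }


def _mode_analysis(values: np.ndarray, circular: bool, bin_width: float = 5.0,
                   min_separation: float = 60.0, min_occupancy: float = 0.05,
                   smooth: int = 3):
    """Histogram the sampled coordinate, watershed it into wells, and return
    (n_occupied_modes, occupancies, centers)."""
    if circular:
        lo, hi = -180.0, 180.0
    else:
        lo, hi = 0.0, 180.0
    nbins = int(round((hi - lo) / bin_width))
    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    h = hist.astype(float)
    # moving-average smoothing (circular wrap for dihedrals)
    kernel = np.ones(2 * smooth + 1) / (2 * smooth + 1)
    if circular:
        h = np.convolve(np.concatenate([h[-smooth:], h, h[:smooth]]), kernel, mode="valid")
    else:
        h = np.convolve(np.pad(h, smooth, mode="edge"), kernel, mode="valid")
    centers = 0.5 * (edges[:-1] + edges[1:])

    # watershed: assign each bin to its uphill local maximum
    n = len(h)
    labels = np.full(n, -1, int)

    def nb(i):
        out = [i - 1, i + 1]
        if circular:
            return [j % n for j in out]
        return [j for j in out if 0 <= j < n]

    order = np.argsort(-h)
    for i in order:
        ups = [j for j in nb(i) if labels[j] >= 0 and h[j] >= h[i]]
        if ups:
            labels[i] = labels[ups[int(np.argmax([h[j] for j in ups]))]]
        else:
            labels[i] = i
    total = hist.sum()
    occ: dict[int, float] = {}
    for i in range(n):
        occ[labels[i]] = occ.get(labels[i], 0.0) + hist[i] / max(total, 1)
    modes = [(centers[k], o) for k, o in occ.items() if o >= min_occupancy]
    modes.sort(key=lambda t: -t[1])
    # merge modes closer than the separation threshold
    merged: list[tuple[float, float]] = []
    for c, o in modes:
        close = False
        for i, (c2, o2) in enumerate(merged):
            d = abs(c - c2)
            if circular:
                d = min(d, 360.0 - d)
            if d < min_separation:
                merged[i] = (c2, o2 + o)
                close = True
                break
        if not close:
            merged.append((c, o))
    merged.sort(key=lambda t: -t[1])
    return len(merged), [round(o, 4) for _, o in merged], [round(c, 1) for c, _ in merged]


def default_monitored(hybrid: Topology, partition: DummyPartition,
                      plan: EditPlan | None = None,
                      junctions=None) -> list[tuple[str, tuple[str, ...]]]:
    """The junction coordinates that betray flapping.

    Monitored per bridge dummy d at bridge atom X: the plan's anchor angle
    and dihedral terms; every *geometric* angle d-X-p to the physical
    neighbors p of X (whether or not an angle term was retained -- the two
    positions of a flapping dummy often agree on the retained angles and
    disagree only on a deleted one); and the wedge dihedrals d-X-p1-p2 whose
    sign distinguishes mirror placements above/below the local plane.
    Orientation dihedrals of deeper dummy atoms (e.g. the spinning of a
    dummy methyl about its own anchor bond between symmetry-equivalent
    wells) are deliberately not monitored.

    For a dual-topology junction only the shared-core neighbors (those that
    actually share an angle term with the dummy bridge atom) are used: the
    other branch moves independently by construction and its relative
    orientation is not a flapping coordinate.
    """
    dummies = partition.dummy_atoms
    g = hybrid.graph()
    mon: list[tuple[str, tuple[str, ...]]] = []
    seen = set()

    def add(kind, atoms):
        if (kind, atoms) not in seen:
            seen.add((kind, atoms))
            mon.append((kind, atoms))

    if plan is not None:
        for s in plan.anchor_schemes:
            for kind, atoms in s.anchor_terms:
                if kind in ("angle", "dihedral"):
                    add(kind, atoms)

    angle_terms = {t.atoms for t in hybrid.angle_terms}
    dual_xs = {j.bridge_atom for j in junctions or [] if j.is_dual_topology}
    for gi, grp in enumerate(partition.dummy_groups):
        for x in sorted(partition.physical_bridge_atoms[gi]):
            bridge = sorted(d for d in grp if g.has_edge(d, x))
            phys_nb = sorted(p for p in g.neighbors(x) if p not in dummies)
            for d in bridge:
                if x in dual_xs:
                    nbs = [p for p in phys_nb
                           if (min(d, p), x, max(d, p)) in angle_terms]
                else:
                    nbs = phys_nb
                for p in nbs:
                    add("angle", (min(d, p), x, max(d, p)))
                for a in range(len(nbs)):
                    for b in range(a + 1, len(nbs)):
                        add("dihedral", (d, x, nbs[a], nbs[b]))
    return mon


def check_flapping(hybrid: Topology, start_coords: np.ndarray | None = None,
                   temperature: float = 300.0, friction: float = 5.0,
                   dt: float = 1.0, steps: int = 500_000, seed: int = 2024,
                   save_interval: int = 50, burn_in_fraction: float = 0.1,
                   monitored: list[tuple[str, tuple[str, ...]]] | None = None,
                   plan: EditPlan | None = None,
                   min_separation: float = 60.0, min_occupancy: float = 0.05,
                   circular_variance_threshold: float = 0.6,
                   minimize_first: bool = True, junctions=None) -> FlappingReport:
    """Langevin run + multimodality analysis of the junction coordinates.

    Defaults follow the gas-phase protocol: 300 K, friction 5/ps, 1 fs time
    step.  ``steps`` at 1 fs gives the run length (500000 = 500 ps).
    """
    partition = partition_dummies(hybrid)
    if monitored is None:
        monitored = default_monitored(hybrid, partition, plan, junctions)
    model = EnergyModel(hybrid)
    x0 = np.asarray(start_coords, float).reshape(-1, 3) if start_coords is not None \
        else hybrid.coords_array()
    if minimize_first:
        x0, _, _ = minimize(model, x0)
    traj = langevin(model, x0, temperature=temperature, friction=friction,
                    dt=dt, steps=steps, seed=seed, save_interval=save_interval)
    burn = int(len(traj.frames) * burn_in_fraction)
    if len(traj.frames) - burn < 10:
        raise ValueError("trajectory shorter than burn-in; increase steps")

    verdicts = []
    for kind, atoms in monitored:
        series = internal_series(traj, model, atoms)[burn:]
        circular = kind == "dihedral"
        n_modes, occs, centers = _mode_analysis(
            series, circular, min_separation=min_separation,
            min_occupancy=min_occupancy)
        cvar = None
        flagged = n_modes > 1
        if circular:
            rad = np.radians(series)
            cvar = float(1.0 - np.abs(np.mean(np.exp(1j * rad))))
            flagged = flagged or cvar > circular_variance_threshold
        verdicts.append(CoordinateVerdict(
            coordinate=atoms, kind=kind, n_modes=n_modes,
            occupancies=occs, mode_centers=centers,
            circular_variance=cvar, flagged=flagged))
    flagged = [v.coordinate for v in verdicts if v.flagged]
    return FlappingReport(monitored=verdicts, flagged=flagged,
                          passed=not flagged, seed=seed, steps=steps)
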