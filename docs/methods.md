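# Methods

## Model and scope

`dummycure` operates on molecular-mechanics topologies with the CHARMM-family
bonded functional forms (no 1/2 prefactors):

| term          | energy                        | units of k            |
|---------------|-------------------------------|-----------------------|
| bond          | k (b − b₀)²                   | kcal mol⁻¹ Å⁻²        |
| angle         | k (θ − θ₀)²                   | kcal mol⁻¹ rad⁻²      |
| Urey–Bradley  | k (s − s₀)²                   | kcal mol⁻¹ Å⁻²        |
| dihedral      | k (1 + cos(nφ − δ)), n ≥ 1    | kcal mol⁻¹            |
| harmonic dih. | k (φ − φ₀)², written n = 0    | kcal mol⁻¹ rad⁻²      |
| improper      | k (ψ − ψ₀)²                   | kcal mol⁻¹ rad⁻²      |

Angles, phases and equilibrium dihedral values are degrees at every public
boundary and radians internally. A harmonic dihedral is encoded as
periodicity 0 with `delta` holding φ₀; this is the "replace the periodic
anchor dihedral by a harmonic one" option for positioning dummy groups.

The analysis layer is purely symbolic: separability verdicts are functions
of the term lists alone (which internal coordinates appear in which retained
terms), never of sampled data. The MM engine exists only for the two
gas-phase checks and the equilibrium-angle calibration. Solvated free energy
simulations, λ-coupling, soft cores and free energy estimators are out of
scope.

## Separability analysis

A dummy atom adjacent to the physical system must be positioned by exactly
three nonredundant bonded terms for its partition-function contribution to
factor out. Five detectors cover the ways redundant terms entangle dummy and
physical coordinates:

* **six-angle**: around a center with m neighbors only 2m − 3 angles are
  independent; an excess is reported only when the coupled set contains both
  purely-physical and dummy-containing angles (dummy-internal redundancy
  factorizes and is deliberately kept for structural integrity).
* **single-/dual-anchored dihedral pairs**: two retained dummy-containing
  dihedrals over one central bond differ by projected angles that are
  functions of the valence angles at the bond's ends. A finding requires
  (i) at least one implicated angle to be purely physical and (ii) every
  dummy-containing implicated angle to exist as a retained term — otherwise
  the projection angle is a free dummy coordinate and no constraint closes.
  Condition (ii) is what makes two dihedral-anchored dummy branches at one
  bridge atom legitimate, with or without the D–X–D angle.
* **Urey–Bradley**: a 1–3 term on an angle with exactly one dummy member
  constrains the purely-physical edge of the triangle; with two dummy
  members it is harmless.
* **coupled three angles**: one bond plus two angles at a branched center is
  nonredundant yet restricts the physical flank angle through the spherical
  relation among the three directions; setting both dummy equilibria to 90°
  removes the effect for all practical purposes (severity `mitigated`).
  Unlike the other four this is a *domain* restriction, not a pointwise
  functional dependence — the numerical rank oracle in the test suite
  cannot see it, and the detector union is therefore compared against the
  oracle without it.
* **mixed impropers** are reported as pure over-determination and deleted by
  best practice; impropers are never used to attach dummies.

The verdict is `separable` with no findings, `separable_mitigated` when only
mitigated findings remain, `coupled` otherwise. Monotonicity (deleting a
dummy term never creates a finding) holds for the four redundancy detectors;
it cannot hold for the three-angle classifier, because deleting the third
X-centered angle is exactly what creates the two-angle pattern.

## Curation rules

Junctions are classified by the number of physical atoms bonded to the
physical bridge atom X. Per class (defaults in parentheses; everything is a
`CurationOptions` field):

* **terminal**: keep all angles; delete one-dummy Urey–Bradley terms; of the
  crossing dihedrals, keep only those terminating at one chosen physical
  atom two bonds from X (heuristic: the heavy atom carrying the longest
  physical chain; overridable per junction).
* **dual, two-angles variant**: anchor the dummy bridge atom by the bridge
  bond plus angles to both physical neighbors at 90° with k = 100
  kcal mol⁻¹ rad⁻² (the 90° choice simultaneously mitigates the three-angle
  constraint and maximizes the flip barrier); delete every dihedral tying
  the bridge dummy into the physical side; prune deeper crossing dihedrals
  to one kept physical atom.
* **dual, dihedral variant**: keep one angle unmodified and one anchor
  dihedral, delete the competing angle; by default the anchor dihedral is
  made single-welled (periodicity 1, k = 100 kcal mol⁻¹, phase chosen so the
  minimum reproduces the reference geometry, snapping to the in-plane value
  for near-planar references). `harden_dihedral=False` reproduces setups
  that deliberately keep the inherited periodic dihedral.
* **dual, two branches**: delete every term mixing the two dummy groups;
  exception: the D–X–D angle may be kept when both branches are
  dihedral-anchored (`keep_dxd_angle`).
* **triple, planar**: disconnect one chosen physical neighbor from the
  dummies entirely; anchor by bond plus two 90°/100 angles to the remaining
  neighbors.
* **triple, nonplanar**: keep all three X-centered dummy angles, soften them
  (k = 3.55 kcal mol⁻¹ rad⁻²) and calibrate their equilibria (below);
  separability is knowingly sacrificed to prevent flapping.
* **dual topology / higher junctions**: verify the branches share no bonded
  terms, then treat each endpoint as a nonplanar triple junction over the
  shared core, with crossing dihedrals kept to exactly one core atom.
* **naive mode** keeps everything (with the physical-endpoint parameters)
  except one-dummy Urey–Bradley terms, and retains mixed impropers.

Plans are idempotent (curating a curated topology yields an empty plan) and
never touch a purely-physical term. `count_modifications` counts terms whose
parameters actually changed; deletions are not counted.

### Equilibrium-angle calibration

For nonplanar triple junctions the soft-angle equilibria are found by
minimizing the hybrid with a probe force constant (0.05 kcal mol⁻¹ rad⁻²) on
the listed angles, reading off the relaxed values, substituting them as new
equilibria, and iterating to the fixed point (tolerance 10⁻⁷ deg, typically
3–4 cycles). At the fixed point the calibrated terms exert exactly zero
force at the joint minimum, so the physical subsystem sits at its own
unperturbed minimum — this is what makes the minimum-invariance check pass
to machine precision. The probe topology has the plan's deletions already
applied, so the calibration sees exactly the terms that survive. Remaining
crossing dihedrals (present for larger dummy groups, e.g. the dual-topology
hybrid) are generally not force-free at the physical minimum; their residual
strain is small at the default force constants but is the reason calibration
cannot make every nonplanar case exact.

## Generic parameter set

The benchmark's original force-field values are not published, so a
transparent generic set is used; all plan-level results (counts, term sets,
verdicts) are independent of the numbers, and the gas-phase checks only need
qualitatively correct stiffnesses.

* bonds: k = 300 kcal mol⁻¹ Å⁻²; b₀ by element pair (C–C 1.53, C–H 1.09,
  N–H 1.01, O–H 0.96, C–N 1.34, C–O 1.41 Å); conjugated (sp²–sp²) C/N bonds
  use the aromatic 1.39 Å so six-membered aromatic rings close as regular,
  strain-free planar hexagons — with element-pair values alone, a ring of
  unequal sides cannot satisfy 120° angles and puckers into mirror minima
  that would spuriously break minimum invariance.
* angles: k = 50 kcal mol⁻¹ rad⁻²; θ₀ = 120° at sp² centers, 106.7° at
  pyramidal amine nitrogens, 109.5° otherwise. The distinct amine value
  mirrors real force fields and is load-bearing: it is what makes
  alkane-inherited dummy angles strain an amine end state in naive setups.
* dihedrals: k = 0.2 kcal mol⁻¹, n = 3 for saturated central bonds;
  k = 1.5 kcal mol⁻¹, n = 2, δ = 180° for conjugated central bonds. The
  stiffer conjugated value keeps rings planar and gives the 2-fold
  substituent torsion a barrier (2k = 3 kcal mol⁻¹) that a dummy group
  crosses many times in a nanosecond-scale gas-phase run.
* hybridization is inferred from element and degree (C with three neighbors
  and N with two are sp²; a one-coordinate O is a carbonyl oxygen), with
  per-atom overrides available.

Hybrid dummy terms are not re-assigned: they inherit the parameters of the
end state where those atoms are physical, translated through the atom map.

## Fixtures

The twelve molecule pairs (alkanes, alcohols, amines, an ether, aromatics
and two tautomer pairs) are built from internal idealized-geometry templates
(zig-zag chains, regular hexagons, tetrahedral/NeRF placement), then
minimized in the generic force field, so every fixture geometry is a true
minimum of its own energy function. Hybrid topologies carry the physical
end state's coordinates; dummy coordinates are transplanted from the partner
state by least-squares superposition of the mapped core and then relaxed
with the physical atoms frozen. Atom maps are pinned explicitly per pair
(they include element-changing pairs such as a chain carbon becoming the
bridge hydrogen), and dummy names follow the benchmark figures (D_C5,
D_H41, D_C, D_H13, …) so that generated edit plans read like the published
tables. The dual-topology acetone/2-propenol hybrid is built directly: a
shared methyl plus two branches that share no bonded terms; the branches
overlap in space, which is physically correct since nothing couples them.

What the fixtures do **not** emulate: solvent, nonbonded interactions
(switched off throughout the validation runs; dummy atoms are always
nonbonded-silent), electrostatics, real CGenFF parameters, and ring
formation/breaking transformations. Passing checks therefore demonstrate the
bonded-term logic — separability bookkeeping, anchoring topology and the
resulting gas-phase behavior — not quantitative free energies of real
systems.

## Gas-phase checks

**Minimum invariance.** The physical molecule is minimized to
max |∇E| ≤ 10⁻⁶ kcal mol⁻¹ Å⁻¹ (L-BFGS, followed when needed by a damped
Newton polish with a finite-difference Hessian, which handles the very soft
probe modes). The hybrid is then started at that physical minimum with
dummies relaxed onto it (physical frozen) and minimized in full; the dummies
are stripped and the physical model evaluated on the remaining coordinates
*without re-minimization*. Pass requires RMSD ≤ 10⁻³ Å (after optimal
superposition) and |ΔE| ≤ 10⁻⁴ kcal mol⁻¹. Starting from the reference
minimum makes the check sharp: for a correctly curated hybrid that point is
already a joint stationary point, and any displacement is attributable to
the dummy terms alone rather than to the minimizer wandering between
symmetry-equivalent rotamer basins.

**Flapping detection.** BAOAB-discretized Langevin dynamics at 300 K,
friction 5 ps⁻¹, 1 fs time step (the discretization is a documented choice,
not a claim about any particular reference implementation). Trajectories
are exactly reproducible from the seed; a numba-compiled kernel is used when
available, with an arithmetically identical numpy fallback. Monitored
coordinates per bridge dummy: the plan's anchor angles/dihedrals, every
*geometric* angle d–X–p to the physical neighbors of X (a deleted angle is
monitored precisely because the two placements of a flapping dummy often
agree on the retained angles and disagree only on the deleted one), and the
wedge dihedrals d–X–p₁–p₂ whose sign distinguishes mirror placements.
Orientation dihedrals of deeper dummy atoms are deliberately not monitored:
a dummy methyl spinning between symmetry-equivalent wells is a rotor, not
flapping. For dual-topology junctions only shared-core neighbors are used
(the other branch moves independently by construction).

A coordinate is flagged when its distribution, after discarding a 10 %
burn-in, occupies more than one well — 5° bins, 3-bin moving-average
smoothing, watershed assignment, wells merged below 60° separation, each
with ≥ 5 % occupancy — or, for dihedrals, when the circular variance
1 − |⟨e^{iφ}⟩| exceeds 0.6 (the free-rotator signature: the coordinate
covers the circle without settling into wells). The thresholds separate
thermal libration from genuine flapping at 300 K with the generic force
constants; they are package conventions, configurable per call. Run lengths
are chosen per barrier: 120–500 ps suffices for the low-barrier flips
(through-plane flips of tetrahedral-angle anchors, the 2-fold ring
dihedral's absence of flips when hardened), while 2–3 ns is used where hop
statistics must converge (the amine two-angle flip at ≈ 5 kcal mol⁻¹
effective barrier; equal-occupancy statistics of the 2-fold anchor wells).

## Numerical choices

* Linear angles and collinear dihedrals: arccos arguments clamped, sin and
  cross-product norms floored at 10⁻¹², giving a defined zero-force limit,
  never NaN.
* Minimization: L-BFGS-B restarts with tight tolerances, then up to 30
  damped Newton steps on the finite-difference Hessian (eigenvalues floored
  in magnitude at 10⁻⁸, step capped at 0.3 Å) — needed because quasi-Newton
  stalls on the 10³-fold stiffness contrast introduced by probe force
  constants.
* Dummy atoms keep their physical masses for dynamics.
* Equipartition on harmonic subsystems holds within the sampling error of
  the runs used (⟨k(b−b₀)²⟩ → k_BT/2); with friction 0 the integrator is
  velocity Verlet and conserves total energy to < 10⁻³ kcal mol⁻¹ drift over
  10⁴ steps at dt = 0.1 fs.
* Two dummy groups on one dual junction are decoupled term-wise; their 90°
  anchors place them on opposite sides of the local physical plane, which
  the relaxation of the transplanted coordinates reproduces.

## Known limitations

* The coupled-three-angles severity depends on exact 90° equilibria
  (tolerance 10⁻⁶ deg); hand-edited near-90° values are classified as
  breaking separability, which is conservative.
* Calibrated equilibria at dual-topology junctions leave the kept crossing
  dihedrals slightly strained (see above); minimum invariance there is exact
  only to the extent those dihedrals are soft.
* The exhaustive element-matched MCS helper is exponential and capped at 16
  atoms; benchmark maps are pinned explicitly, including element-changing
  pairs the MCS would never propose.
* Ring closure/breaking transformations, restraint-based whole-molecule dual
  topology and QM/MM setups are out of scope.
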