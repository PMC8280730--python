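# dummycure

Correct handling of **dummy atoms** in single- and dual-topology alchemical
free energy setups: junction classification, symbolic detection of bonded
couplings that break partition-function separability, automatic generation of
bonded-term edit plans, and gas-phase validation checks backed by a minimal
molecular-mechanics engine.

## The problem

In relative free energy calculations one end state usually has atoms the
other lacks. The missing atoms persist as *dummy atoms*: particles with no
nonbonded interactions, attached to the physical molecule only through bonded
terms. Dummy contributions cancel from double free energy differences
(ΔΔA = ΔA₂′ − ΔA₁′) only if the partition function factorizes,

  Z(L^D) = Z(L) · Z(D),

which requires each dummy atom near the physical system to be held by
**exactly three nonredundant internal coordinates** (one bond, plus angles
and/or a dihedral). Routine setups instead keep every force-field term
generated from the connectivity, and the redundant terms create algebraic
constraints that entangle dummy and physical coordinates — for example:

* *six-angle constraints*: a center with m neighbors supports only 2m − 3
  independent angles; keeping all of them couples the dummy angles to the
  physical ones;
* *single/dual-anchored dihedral pairs*: two retained dihedrals over the same
  central bond differ by a projected angle that is a function of physical
  valence angles;
* *Urey–Bradley 1–3 terms* with one dummy member, which close a triangle over
  a physical edge;
* a dummy anchored by one bond plus two angles at a branched center, which
  constrains the physical flank angle unless both equilibrium angles are set
  to 90°.

Conversely, pruning *too much* lets the dummy group **flap** between several
Cartesian placements that satisfy the same internal coordinates (periodic
anchor dihedrals, missing third angles, anchors riding on freely rotating
methyl groups), destroying convergence of ⟨∂U/∂λ⟩ near the end states.

`dummycure` classifies each attachment site (the physical bridge atom X) by
its number of physical neighbors — terminal (1), dual (2), triple (3,
planar or pyramidal), or higher/dual-topology — and emits the best-practice
edit plan per class: which dihedrals to delete, which anchor angles to move
to 90° with a hard force constant, when to soften and re-calibrate angle
equilibria at a nonplanar triple junction (force constant 3.55
kcal mol⁻¹ rad⁻², equilibria from a probe-force-constant minimization), and
how a dual-topology hybrid reduces to a pair of nonplanar triple junctions.
Two quick gas-phase checks validate the result: **minimum invariance** (the
physical minimum must be bit-identical with and without dummies) and
**flapping detection** (well analysis of junction coordinates over a short
Langevin trajectory).

## Worked example

The methane → ammonia transformation leaves one dummy hydrogen on a
pyramidal nitrogen — a *nonplanar triple junction*, the one case where
separability must be sacrificed to prevent flapping:

```
$ dummycure pipeline --fixture MET2AMM-1 --steps 100000 --seed 7 --out report.json
MET2AMM-1[B]: separability=coupled min_invariance=pass flapping=pass
```

The plan keeps all three H–N–D angles but softens them, with equilibria
calibrated so the physical ammonia minimum is untouched:

```
mod: D_H4-N-H1 [50.0, 109.5] -> [3.55, 112.11766043815895]
mod: D_H4-N-H2 [50.0, 109.5] -> [3.55, 112.11766043815882]
mod: D_H4-N-H3 [50.0, 109.5] -> [3.55, 112.11766043816091]
```

Three modified terms (the printed n_mod for this transformation); the
112.12° equilibria place the dummy on the C₃ᵥ axis of the relaxed amine so
the calibrated terms exert zero force there (min-invariance RMSD ≈ 2·10⁻¹³ Å),
while the verdict stays `coupled` because the retained sixth angle couples
θ(H–N–D) to θ(H–N–H) — exactly the documented trade-off. The naive variant
fails the same check (`dummycure pipeline --fixture MET2AMM-3` exits 1).

A dual junction instead curates cleanly:

```
$ dummycure curate --fixture TOL2PYR-1 --markdown
| Deleted        | Modified                       |
|---             |---                             |
| C2-C1-N-D_C    | C1-N-D_C  (90 deg, k raised)   |
| C4-C5-N-D_C    | C5-N-D_C  (90 deg, k raised)   |
| C5-N-D_C-D_H1  |                                |
| C5-N-D_C-D_H2  |                                |
| C5-N-D_C-D_H3  |                                |
| D_C-N-C1-H1    |                                |
| D_C-N-C5-H5    |                                |
```

seven deletions and two 90°-angle modifications — the published treatment of
the toluene → pyridine dual junction.

All 24 benchmark transformation labels are built programmatically
(`dummycure fixtures list`), with atom names matching the published figures
(H32, D_C5, D_H41, …).

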