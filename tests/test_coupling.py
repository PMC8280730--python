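"""Constraint detectors and the separability verdict.

The reference methane-endpoint system with two dummy hydrogens (the
methylamine-to-methane transformation) is built from the molecule templates:
methylamine's nitrogen maps onto methane's H4, and the two amine hydrogens
become dummies D_HN1 / D_HN2 bonded to H4.
"""

import itertools

import pytest

from _oracles import mixed_dependence
from dummycure import fixtures as fx
from dummycure.alchemy import AtomMap, build_hybrid, partition_dummies
from dummycure.coupling import (
    BREAKS,
    MITIGATED,
    all_findings,
    detect_coupled_three_angles,
    detect_dihedral_couplings,
    detect_redundant_impropers,
    detect_six_angle,
    detect_urey_bradley,
    separability_verdict,
)
from dummycure.molgraph import AngleTerm, DihedralTerm, ImproperTerm, UreyBradleyTerm


@pytest.fixture(scope="module")
def mta2met():
    """Methane endpoint of methylamine -> methane, dummies on H4."""
    mta = fx.methylamine().topology()
    met = fx.methane().topology()
    amap = AtomMap([("C", "C"), ("HC1", "H1"), ("HC2", "H2"), ("HC3", "H3"),
                    ("N", "H4")])
    return fx._hybrid_with_coords(mta, met, amap, "B")


def dihedral(top, atoms):
    t = top.find_term("dihedral", atoms)
    assert t is not None, atoms
    return t


class TestSixAngle:
    def test_ammonia_with_all_six_angles_couples(self, fixture_cache):
        hyb = fixture_cache("MET2AMM-1").hybrids["B"]
        findings = detect_six_angle(hyb, hyb.dummy_atoms())
        assert len(findings) == 1
        f = findings[0]
        assert f.severity == BREAKS
        # the physical H-N-H angles are implicated
        assert all(not set(a) & hyb.dummy_atoms() for a in f.physical_dofs)
        assert len(f.physical_dofs) == 3

    def test_five_angles_are_nonredundant(self, fixture_cache):
        hyb = fixture_cache("MET2AMM-1").hybrids["B"].copy()
        victim = AngleTerm(("D_H4", "N", "H1"), 1, 0).atoms
        hyb.angle_terms = [t for t in hyb.angle_terms if t.atoms != victim]
        assert detect_six_angle(hyb, hyb.dummy_atoms()) == []

    def test_dummy_only_redundancy_is_harmless(self, fixture_cache):
        """Terminal junction with three dummy branches: all six angles around
        the bridge atom involve dummies, so the constraint factorizes."""
        hyb = fixture_cache("TOL2MET").hybrids["B"]
        assert detect_six_angle(hyb, hyb.dummy_atoms()) == []


class TestDihedralCouplings:
    def test_single_anchored_pair(self, mta2met):
        top = mta2met.copy()
        keep = {dihedral(top, ("D_HN1", "H4", "C", "H1")).atoms,
                dihedral(top, ("D_HN1", "H4", "C", "H3")).atoms}
        top.dihedral_terms = [t for t in top.dihedral_terms
                              if not set(t.atoms) & {"D_HN1", "D_HN2"}
                              or t.atoms in keep]
        findings = detect_dihedral_couplings(top, top.dummy_atoms())
        assert [f.kind for f in findings] == ["single_anchored_dihedral"]
        implicated = {tuple(a) for a in findings[0].physical_dofs}
        assert ("H1", "C", "H3") in implicated  # the projected angle
        assert ("H1", "C", "H4") in implicated and ("H3", "C", "H4") in implicated

    def test_dual_anchored_pair(self, mta2met):
        top = mta2met.copy()
        keep = {dihedral(top, ("D_HN1", "H4", "C", "H1")).atoms,
                dihedral(top, ("D_HN2", "H4", "C", "H3")).atoms}
        top.dihedral_terms = [t for t in top.dihedral_terms
                              if not set(t.atoms) & {"D_HN1", "D_HN2"}
                              or t.atoms in keep]
        kinds = {f.kind for f in detect_dihedral_couplings(top, top.dummy_atoms())}
        assert kinds == {"dual_anchored_dihedral"}

    def test_pruned_to_one_physical_atom_is_clean(self, mta2met):
        top = mta2met.copy()
        keep = {dihedral(top, ("D_HN1", "H4", "C", "H1")).atoms,
                dihedral(top, ("D_HN2", "H4", "C", "H1")).atoms}
        top.dihedral_terms = [t for t in top.dihedral_terms
                              if not set(t.atoms) & {"D_HN1", "D_HN2"}
                              or t.atoms in keep]
        assert detect_dihedral_couplings(top, top.dummy_atoms()) == []


class TestUreyBradley:
    def test_one_dummy_member_breaks(self, fixture_cache):
        hyb = fixture_cache("MET2WAT").hybrids["B"].copy()
        hyb.urey_bradley_terms = [UreyBradleyTerm(("H1", "D_H3"), 30.0, 1.7)]
        findings = detect_urey_bradley(hyb, hyb.dummy_atoms())
        assert len(findings) == 1 and findings[0].severity == BREAKS
        # the physical O-H edge is what gets constrained
        assert set(findings[0].physical_dofs[0]) == {"H1", "O"}

    def test_two_dummy_members_harmless(self, fixture_cache):
        hyb = fixture_cache("MET2WAT").hybrids["B"].copy()
        hyb.urey_bradley_terms = [UreyBradleyTerm(("D_H3", "D_H4"), 30.0, 1.7)]
        assert detect_urey_bradley(hyb, hyb.dummy_atoms()) == []

    def test_no_ub_terms_no_findings(self, fixture_cache):
        hyb = fixture_cache("MET2WAT").hybrids["B"]
        assert detect_urey_bradley(hyb, hyb.dummy_atoms()) == []


class TestCoupledThreeAngles:
    def test_tetrahedral_equilibria_break(self, fixture_cache):
        # water endpoint before curation: dummy held by bond + two angles at
        # their inherited tetrahedral equilibria
        hyb = fixture_cache("MET2WAT").hybrids["B"].copy()
        gone = AngleTerm(("D_H3", "O", "D_H4"), 1, 0).atoms
        hyb.angle_terms = [t for t in hyb.angle_terms if t.atoms != gone]
        findings = detect_coupled_three_angles(hyb, hyb.dummy_atoms())
        assert {f.severity for f in findings} == {BREAKS}
        assert all(f.physical_dofs == (("H1", "O", "H2"),) for f in findings)

    def test_right_angles_mitigate(self, curated_cache):
        from dummycure.curation import apply_plan

        hyb, part, junc, plan = curated_cache("MET2WAT", "B")
        cur = apply_plan(hyb, plan)
        findings = detect_coupled_three_angles(cur, cur.dummy_atoms())
        assert findings and {f.severity for f in findings} == {MITIGATED}

    def test_dihedral_anchoring_not_this_pattern(self, curated_cache):
        from dummycure.curation import apply_plan

        hyb, part, junc, plan = curated_cache("TOL2PYR-2", "B")
        cur = apply_plan(hyb, plan)
        assert detect_coupled_three_angles(cur, cur.dummy_atoms()) == []


class TestImpropers:
    def test_mixed_improper_reported(self, fixture_cache):
        hyb = fixture_cache("TOL2PYR-1").hybrids["B"].copy()
        hyb.improper_terms = [ImproperTerm(("N", "C1", "C5", "D_C"), 10.0, 0.0)]
        findings = detect_redundant_impropers(hyb, hyb.dummy_atoms())
        assert [f.kind for f in findings] == ["redundant_count"]


class TestVerdict:
    def test_physical_molecule_is_separable(self):
        top = fx.water().topology()
        part = partition_dummies(top, dummy_atoms=set())
        assert separability_verdict(top, part)[0] == "separable"

    def test_curated_terminal_separable(self, curated_cache):
        from dummycure.curation import apply_plan

        hyb, part, junc, plan = curated_cache("HEX2PRP-1", "B")
        assert separability_verdict(apply_plan(hyb, plan), part)[0] == "separable"

    def test_nonplanar_triple_stays_coupled(self, curated_cache):
        """Keeping three soft angles deliberately sacrifices separability."""
        from dummycure.curation import apply_plan

        hyb, part, junc, plan = curated_cache("MET2AMM-1", "B")
        assert separability_verdict(apply_plan(hyb, plan), part)[0] == "coupled"


class TestOracleAgreement:
    """The union of the rank-detectable detectors (six-angle, dihedral pairs,
    Urey-Bradley) must agree with a numerical Jacobian-dependence oracle.

    The bond-plus-two-angles constraint is excluded: it restricts the
    accessible domain of the physical flank angle rather than creating a
    pointwise functional dependence, so only the symbolic detector sees it.
    """

    def _rank_detectable(self, top):
        dummies = top.dummy_atoms()
        return (detect_six_angle(top, dummies)
                + detect_dihedral_couplings(top, dummies)
                + detect_urey_bradley(top, dummies))

    @pytest.mark.parametrize("label", ["MET2AMM-3", "MET2WAT"])
    def test_small_hybrids_naive(self, fixture_cache, label):
        hyb = fixture_cache(label).hybrids["B"]
        assert bool(self._rank_detectable(hyb)) == mixed_dependence(hyb, hyb.dummy_atoms())

    def test_dihedral_subsets(self, mta2met):
        """All subsets of the four crossing dihedrals of the two-dummy
        methane endpoint (intra-dummy terms always retained)."""
        crossing = [t.atoms for t in mta2met.dihedral_terms
                    if {"D_HN1", "D_HN2"} & set(t.atoms)
                    and not {"D_HN1", "D_HN2"} >= set(t.atoms)]
        # drop the six-angle redundancy so only dihedral effects remain
        top0 = mta2met.copy()
        victim = AngleTerm(("D_HN1", "H4", "D_HN2"), 1, 0).atoms
        top0.angle_terms = [t for t in top0.angle_terms if t.atoms != victim]
        for r in range(len(crossing) + 1):
            for keep in itertools.combinations(crossing, r):
                top = top0.copy()
                top.dihedral_terms = [
                    t for t in top0.dihedral_terms
                    if t.atoms not in crossing or t.atoms in keep
                ]
                got = bool(self._rank_detectable(top))
                want = mixed_dependence(top, top.dummy_atoms())
                assert got == want, f"subset {keep}"

    def test_curated_states_are_clean_for_oracle(self, curated_cache):
        from dummycure.curation import apply_plan

        for label in ("MET2WAT",):
            hyb, part, junc, plan = curated_cache(label, "B")
            cur = apply_plan(hyb, plan)
            assert not self._rank_detectable(cur)
            assert not mixed_dependence(cur, cur.dummy_atoms())


class TestMonotonicity:
    def test_deleting_dummy_terms_never_adds_redundancy_findings(self, fixture_cache):
        """The redundancy detectors (six-angle, dihedral pairs, Urey-Bradley,
        impropers) are monotone: removing a dummy term can only remove
        findings.  The bond-plus-two-angles classifier is excluded -- deleting
        the third angle at a nonplanar triple junction genuinely *switches*
        the anchoring into the two-angle pattern, which is a different
        finding, not a redundancy created by deletion."""
        import numpy as np

        def monotone(top, dummies):
            return set(
                detect_six_angle(top, dummies)
                + detect_dihedral_couplings(top, dummies)
                + detect_urey_bradley(top, dummies)
                + detect_redundant_impropers(top, dummies)
            )

        for label in ("MET2AMM-3", "MET2WAT", "TOL2PYR-1"):
            hyb = fixture_cache(label).hybrids["B"]
            dummies = hyb.dummy_atoms()
            before = monotone(hyb, dummies)
            rng = np.random.default_rng(11)
            candidates = [t for t in hyb.angle_terms + hyb.dihedral_terms
                          if set(t.atoms) & dummies]
            for t in rng.choice(len(candidates), size=min(6, len(candidates)),
                                replace=False):
                victim = candidates[int(t)]
                top = hyb.copy()
                top.angle_terms = [a for a in top.angle_terms if a is not victim]
                top.dihedral_terms = [d for d in top.dihedral_terms if d is not victim]
                assert monotone(top, dummies) <= before
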