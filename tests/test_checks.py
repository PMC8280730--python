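"""The two gas-phase validation checks."""

import numpy as np
import pytest

from dummycure import fixtures as fx
from dummycure.alchemy import classify_junctions, partition_dummies
from dummycure.checks import check_flapping, check_min_invariance, strip_dummies
from dummycure.curation import CurationOptions, apply_plan, curate
from dummycure.molgraph import AngleTerm


def curated(fp, ep, opts=None):
    hybrid = fp.hybrids[ep]
    part = partition_dummies(hybrid, endpoint=ep)
    junc = classify_junctions(hybrid, part, reference_coords=hybrid.coords_array(),
                              dual_topology_bridges={"C3"} if fp.dual_topology else set())
    plan = curate(hybrid, part, junc, opts if opts is not None else fp.options[ep])
    return apply_plan(hybrid, plan), plan, junc


class TestMinInvariance:
    def test_best_practice_amine_passes(self, fixture_cache):
        fp = fixture_cache("MET2AMM-1")
        cur, plan, junc = curated(fp, "B")
        report = check_min_invariance(fp.top_b, cur)
        assert report.passed
        assert report.rmsd <= 1e-3

    def test_naive_amine_fails_with_distorted_angles(self, fixture_cache):
        """Methane-inherited dummy angles strain the physical pyramid."""
        fp = fixture_cache("MET2AMM-3")
        cur, plan, junc = curated(fp, "B")
        report = check_min_invariance(fp.top_b, cur)
        assert not report.passed
        # the physical H-N-H angles are measurably distorted
        assert max(report.per_coordinate.values()) > 0.1

    def test_zero_dummy_hybrid_passes_trivially(self):
        top = fx.water().topology()
        report = check_min_invariance(top, top.copy())
        assert report.passed
        assert report.rmsd == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("label", ["HEX2PRP-1", "TOL2PYR-1", "TOL2PYR-2",
                                       "MET2WAT", "ACE2PEOL-1", "PHE2CYC"])
    def test_best_practice_fixtures_pass(self, fixture_cache, label):
        fp = fixture_cache(label)
        for ep in fp.dummy_endpoints:
            cur, plan, junc = curated(fp, ep)
            physical = fp.top_a if ep == "A" else fp.top_b
            assert check_min_invariance(physical, cur).passed, (label, ep)

    def test_strip_dummies_removes_all_dummy_terms(self, fixture_cache):
        hyb = fixture_cache("TOL2PYR-1").hybrids["B"]
        stripped, x = strip_dummies(hyb, hyb.coords_array())
        assert stripped.dummy_atoms() == set()
        assert x.shape == (stripped.n_atoms, 3)
        for t in stripped.all_terms():
            assert not any(a.startswith("D_") for a in t.atoms)


class TestFlapping:
    STEPS = 120_000  # 120 ps at 1 fs

    def test_two_fold_anchor_dihedral_flaps_between_two_wells(self, fixture_cache):
        """With only the bond / angle / inherited 2-fold dihedral active on
        the dummy bridge atom, the dummy methyl hops between the outside and
        inside-the-ring positions with comparable probability."""
        fp = fixture_cache("TOL2PYR-2")
        cur, plan, junc = curated(
            fp, "B", CurationOptions(dual_anchor="dihedral", harden_dihedral=False,
                                     keep_atom={"N": "C1"}))
        # the reduced force field of the pathology: the methyl hydrogens ride
        # on intra-group terms alone, nothing else orients the group
        cur.dihedral_terms = [t for t in cur.dihedral_terms
                              if not (set(t.atoms) & {"D_H1", "D_H2", "D_H3"}
                                      and "C1" in t.atoms)]
        rep = check_flapping(cur, steps=3_000_000, seed=2024, plan=plan, junctions=junc)
        assert not rep.passed
        anchor = next(v for v in rep.monitored
                      if v.kind == "dihedral" and set(v.coordinate) == {"C2", "C1", "N", "D_C"})
        assert anchor.n_modes == 2
        assert all(0.35 <= occ <= 0.65 for occ in anchor.occupancies[:2])

    def test_periodicity_one_hard_anchor_does_not_flap(self, fixture_cache):
        fp = fixture_cache("TOL2PYR-2")
        cur, plan, junc = curated(fp, "B")
        rep = check_flapping(cur, steps=self.STEPS, seed=2024, plan=plan, junctions=junc)
        assert rep.passed

    def test_two_angle_amine_anchoring_flaps(self, fixture_cache):
        """With the third H-N-D angle deleted the dummy swaps between the
        methane-like position and a position on top of that hydrogen."""
        fp = fixture_cache("MET2AMM-3")
        cur, plan, junc = curated(fp, "B", CurationOptions(mode="naive"))
        victim = AngleTerm(("D_H4", "N", "H3"), 1, 0).atoms
        cur.angle_terms = [t for t in cur.angle_terms if t.atoms != victim]
        rep = check_flapping(cur, steps=2_000_000, seed=2024, plan=plan, junctions=junc)
        assert not rep.passed
        flagged = {"-".join(v.coordinate) for v in rep.monitored if v.flagged}
        assert "D_H4-N-H3" in flagged  # the deleted angle's coordinate

    def test_three_soft_calibrated_angles_do_not_flap(self, fixture_cache):
        fp = fixture_cache("MET2AMM-1")
        cur, plan, junc = curated(fp, "B")
        rep = check_flapping(cur, steps=2_000_000, seed=2024, plan=plan, junctions=junc)
        assert rep.passed

    def test_non_right_angle_dual_anchoring_flips_through_plane(self, fixture_cache):
        """Bond + two angles at tetrahedral equilibria leave two mirror
        placements; 90-degree equilibria raise the barrier and stop it."""
        fp = fixture_cache("MET2WAT")
        cur, plan, junc = curated(fp, "B")
        soft = cur.copy()
        soft.angle_terms = [
            AngleTerm(t.atoms, 50.0, 109.5) if set(t.atoms) & soft.dummy_atoms()
            else t
            for t in soft.angle_terms
        ]
        rep = check_flapping(soft, steps=500_000, seed=2024, plan=plan, junctions=junc)
        assert not rep.passed
        rep90 = check_flapping(cur, steps=self.STEPS, seed=2024, plan=plan, junctions=junc)
        assert rep90.passed

    def test_free_rotator_anchor_is_flagged_by_circular_variance(self, fixture_cache):
        """A dihedral anchored in a spinning methyl group drags the dummy
        through rotamer interconversions."""
        fp = fixture_cache("PRP2DIM-2")
        cur, plan, junc = curated(fp, "B")
        rep = check_flapping(cur, steps=self.STEPS, seed=2024, plan=plan, junctions=junc)
        assert not rep.passed
        anchors = [v for v in rep.monitored
                   if v.kind == "dihedral" and v.flagged and v.circular_variance]
        assert any(v.circular_variance > 0.6 for v in anchors)

    def test_verdicts_stable_across_seeds(self, fixture_cache):
        fp = fixture_cache("TOL2PYR-2")
        patho_opts = CurationOptions(dual_anchor="dihedral", harden_dihedral=False,
                                     keep_atom={"N": "C1"})
        for seed in (1, 2, 3):
            cur, plan, junc = curated(fp, "B", patho_opts)
            assert not check_flapping(cur, steps=400_000, seed=seed,
                                      plan=plan, junctions=junc).passed
            cur, plan, junc = curated(fp, "B")
            assert check_flapping(cur, steps=self.STEPS, seed=seed,
                                  plan=plan, junctions=junc).passed

    def test_short_trajectory_errors(self, fixture_cache):
        fp = fixture_cache("MET2WAT")
        cur, plan, junc = curated(fp, "B")
        with pytest.raises(ValueError, match="burn-in"):
            check_flapping(cur, steps=100, seed=0, plan=plan, junctions=junc)
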