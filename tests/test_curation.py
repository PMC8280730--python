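"""Edit-plan generation, application and calibration."""

import numpy as np
import pytest

from dummycure import fixtures as fx
from dummycure.curation import (
    CurationOptions,
    apply_plan,
    calibrate_equilibrium_angles,
    count_modifications,
    curate,
)
from dummycure.molgraph import TopologyError


class TestWorkedExamples:
    """The four published worked examples: exact Deleted/Modified set
    equality between the engine's plan and the printed tables."""

    @pytest.mark.parametrize("label", ["HEX2PRP-1", "TOL2PYR-1", "TOL2PYR-2",
                                       "ACE2PEOL-1"])
    def test_plan_matches_published_table(self, curated_cache, label):
        expected = fx.expected_plan(label)
        for ep, exp in expected.items():
            hybrid, part, junc, plan = curated_cache(label, ep)
            assert set(plan.deletions) == exp["deleted"], ep
            assert {(m.kind, m.atoms) for m in plan.modifications} == exp["modified"], ep

    def test_tol2pyr1_modifications_are_right_angles(self, curated_cache):
        _, _, _, plan = curated_cache("TOL2PYR-1", "B")
        for m in plan.modifications:
            assert m.new_params == (100.0, 90.0)

    def test_tol2pyr2_anchor_dihedral_hardened(self, curated_cache):
        _, _, _, plan = curated_cache("TOL2PYR-2", "B")
        (m,) = plan.modifications
        k, n, delta = m.new_params
        assert (k, n) == (100.0, 1)
        # the single minimum must sit at the in-plane, outside-the-ring
        # position (trans to C2), i.e. phase 0 for the CHARMM 1 + cos form
        assert delta == 0.0


class TestCounts:
    @pytest.mark.parametrize("label", fx.FIXTURE_LABELS)
    def test_dummy_and_modification_counts(self, fixture_cache, curated_cache, label):
        """n_dum and n_mod reproduce the published per-transformation
        bookkeeping under the documented options."""
        fp = fixture_cache(label)
        assert max(fp.n_dum_by_endpoint.values()) == fp.expected_n_dum
        total = sum(
            count_modifications(curated_cache(label, ep)[3])
            for ep in fp.dummy_endpoints
        )
        assert total == fp.expected_n_mod


class TestPlanProperties:
    @pytest.mark.parametrize("label", ["HEX2PRP-1", "TOL2PYR-1", "MET2WAT",
                                       "MET2AMM-1", "ACE2PEOL-2", "HEX2POL-1"])
    def test_purely_physical_terms_untouched(self, curated_cache, label):
        hybrid, part, junc, plan = curated_cache(label, "B")
        cur = apply_plan(hybrid, plan)
        dummies = part.dummy_atoms
        before = {(k, t.atoms, t.params)
                  for k, terms in [("b", hybrid.bond_terms), ("a", hybrid.angle_terms),
                                   ("d", hybrid.dihedral_terms)]
                  for t in terms if not set(t.atoms) & dummies}
        after = {(k, t.atoms, t.params)
                 for k, terms in [("b", cur.bond_terms), ("a", cur.angle_terms),
                                  ("d", cur.dihedral_terms)]
                 for t in terms if not set(t.atoms) & dummies}
        assert before == after

    @pytest.mark.parametrize("label", ["TOL2PYR-1", "TOL2PYR-2", "MET2WAT",
                                       "HEX2POL-1", "PRP2DIM-1"])
    def test_bridge_dummies_held_by_three_anchor_terms(self, curated_cache, label):
        for s in curated_cache(label, "B")[3].anchor_schemes:
            if s.variant in ("bond_two_angles", "bond_angle_dihedral"):
                assert len(s.anchor_terms) == 3, s

    @pytest.mark.parametrize("label", ["HEX2PRP-1", "TOL2MET", "ETH2AMM-1"])
    def test_interior_dummies_keep_all_intra_group_terms(self, curated_cache, label):
        """Within a dummy group, every bonded interaction survives."""
        hybrid, part, junc, plan = curated_cache(label, "B")
        cur = apply_plan(hybrid, plan)
        dummies = part.dummy_atoms
        intra_before = [t.atoms for t in hybrid.angle_terms + hybrid.dihedral_terms
                        if set(t.atoms) <= dummies]
        intra_after = [t.atoms for t in cur.angle_terms + cur.dihedral_terms
                       if set(t.atoms) <= dummies]
        assert intra_before == intra_after

    @pytest.mark.parametrize("label", ["HEX2PRP-1", "TOL2PYR-1", "TOL2PYR-2",
                                       "MET2WAT", "MET2AMM-1", "ACE2PEOL-1"])
    def test_idempotence(self, fixture_cache, curated_cache, label):
        """Curating an already-curated topology produces an empty plan."""
        from dummycure.alchemy import classify_junctions, partition_dummies

        fp = fixture_cache(label)
        for ep in fp.dummy_endpoints:
            hybrid, part, junc, plan = curated_cache(label, ep)
            cur = apply_plan(hybrid, plan)
            part2 = partition_dummies(cur, endpoint=ep)
            junc2 = classify_junctions(cur, part2,
                                       reference_coords=cur.coords_array())
            plan2 = curate(cur, part2, junc2, fp.options[ep])
            assert plan2.deletions == []
            assert count_modifications(plan2) == 0

    def test_naive_mode_only_deletes_single_dummy_ub(self, fixture_cache):
        from dummycure.alchemy import classify_junctions, partition_dummies
        from dummycure.molgraph import UreyBradleyTerm

        hyb = fixture_cache("MET2WAT").hybrids["B"].copy()
        hyb.urey_bradley_terms = [UreyBradleyTerm(("H1", "D_H3"), 30.0, 1.7),
                                  UreyBradleyTerm(("D_H3", "D_H4"), 30.0, 1.7)]
        part = partition_dummies(hyb, endpoint="B")
        junc = classify_junctions(hyb, part, reference_coords=hyb.coords_array())
        plan = curate(hyb, part, junc, CurationOptions(mode="naive"))
        assert plan.deletions == [("ureybradley", ("D_H3", "H1"))]
        assert plan.modifications == []

    def test_higher_junction_without_declaration_errors(self, fixture_cache):
        from dummycure.alchemy import classify_junctions, partition_dummies

        fp = fixture_cache("ACE2PEOL-2")
        hyb = fp.hybrids["A"]
        part = partition_dummies(hyb, endpoint="A")
        junc = classify_junctions(hyb, part, reference_coords=hyb.coords_array())
        # without the dual-topology declaration the quadruple junction must
        # be refused with guidance
        with pytest.raises(TopologyError, match="dual-topology"):
            curate(hyb, part, junc, CurationOptions())

    def test_apply_plan_unknown_term_errors(self, curated_cache):
        hybrid, part, junc, plan = curated_cache("TOL2PYR-1", "B")
        cur = apply_plan(hybrid, plan)
        with pytest.raises(TopologyError, match="unknown"):
            apply_plan(cur, plan)  # deletions already applied

    def test_empty_plan_is_identity(self, fixture_cache):
        from dummycure.curation import EditPlan
        from dummycure.molgraph import topology_to_json

        hyb = fixture_cache("MET2WAT").hybrids["B"]
        out = apply_plan(hyb, EditPlan(endpoint="B", mode="best_practice"))
        assert topology_to_json(out) == topology_to_json(hyb)
        assert count_modifications(EditPlan(endpoint="B", mode="best_practice")) == 0


class TestCalibration:
    def test_c3v_symmetry_gives_equal_angles(self, fixture_cache):
        hyb = fixture_cache("MET2AMM-1").hybrids["B"]
        soft = [t.atoms for t in hyb.angle_terms if "D_H4" in t.atoms]
        theta0 = calibrate_equilibrium_angles(hyb, soft)
        vals = list(theta0.values())
        assert np.ptp(vals) < 1e-5

    def test_calibrated_value_regression(self, fixture_cache):
        """Frozen reference from an independent steepest-descent minimizer:
        for the generic amine parameters (H-N-H equilibrium 106.7 deg) the
        probe-relaxed dummy angle settles at 112.118 deg on the C3 axis."""
        hyb = fixture_cache("MET2AMM-1").hybrids["B"]
        soft = [t.atoms for t in hyb.angle_terms if "D_H4" in t.atoms]
        theta0 = calibrate_equilibrium_angles(hyb, soft)
        for v in theta0.values():
            assert v == pytest.approx(112.118, abs=1e-2)

    def test_physical_minimum_unchanged_after_substitution(self, curated_cache):
        from dummycure.checks import check_min_invariance

        hybrid, part, junc, plan = curated_cache("MET2AMM-1", "B")
        cur = apply_plan(hybrid, plan)
        physical = fx.ammonia().topology()
        report = check_min_invariance(physical, cur)
        assert report.passed

    def test_empty_request_returns_empty(self, fixture_cache):
        hyb = fixture_cache("MET2AMM-1").hybrids["B"]
        assert calibrate_equilibrium_angles(hyb, []) == {}

    def test_missing_term_errors(self, fixture_cache):
        hyb = fixture_cache("MET2AMM-1").hybrids["B"]
        with pytest.raises(TopologyError, match="not present"):
            calibrate_equilibrium_angles(hyb, [("D_H4", "N", "ZZ")])
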