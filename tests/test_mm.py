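"""Energy model, minimizer and Langevin integrator."""

import numpy as np
import pytest

from dummycure import fixtures as fx
from dummycure.mm import (
    ACC,
    KB,
    EnergyModel,
    langevin,
    measure_angle,
    minimize,
)
from dummycure.molgraph import Atom, BondTerm, Topology


def two_atom_bond(k=300.0, b0=1.0):
    top = Topology()
    top.add_atom(Atom(id="a", element="C", coords=(0.0, 0.0, 0.0)))
    top.add_atom(Atom(id="b", element="C", coords=(b0, 0.0, 0.0)))
    top.add_bond("a", "b")
    top.bond_terms = [BondTerm(("a", "b"), k, b0)]
    return top


class TestEnergy:
    def test_equilibrium_energy_is_zero(self):
        # water: bond lengths and the single angle can sit exactly at their
        # equilibria, so the bonded energy vanishes at the minimum
        top = fx.water().topology()
        m = EnergyModel(top)
        x, e, _ = minimize(m, top.coords_array())
        assert e == pytest.approx(0.0, abs=1e-10)
        # methane is slightly frustrated (six 109.5-degree targets on a
        # tetrahedral star) but stays within numerical noise of zero
        met = fx.methane().topology()
        _, e_met, _ = minimize(EnergyModel(met), met.coords_array())
        assert 0 <= e_met < 1e-3

    def test_single_bond_stretch(self):
        # E = k (b - b0)^2, no 1/2: k=300, displacement 0.1 A -> 3.0 kcal/mol
        top = two_atom_bond()
        m = EnergyModel(top)
        e, breakdown = m.energy(np.array([[0, 0, 0], [1.1, 0, 0]], float))
        assert e == pytest.approx(3.0)
        assert breakdown["bond"] == pytest.approx(3.0)

    def test_breakdown_sums_to_total(self, fixture_cache):
        hyb = fixture_cache("TOL2PYR-1").hybrids["B"]
        m = EnergyModel(hyb)
        e, breakdown = m.energy(hyb.coords_array())
        assert e == pytest.approx(sum(breakdown.values()))

    @pytest.mark.parametrize("label", ["MET2AMM-1", "TOL2PYR-1", "ACE2PEOL-2"])
    def test_gradient_matches_finite_differences(self, fixture_cache, label):
        hyb = fixture_cache(label).hybrids["B"]
        m = EnergyModel(hyb)
        rng = np.random.default_rng(5)
        x = hyb.coords_array() + 0.05 * rng.standard_normal((hyb.n_atoms, 3))
        _, g, _ = m.energy_and_gradient(x)
        h = 1e-5
        num = np.zeros_like(g)
        for i in range(x.shape[0]):
            for d in range(3):
                xp = x.copy(); xp[i, d] += h
                xm = x.copy(); xm[i, d] -= h
                num[i, d] = (m.energy(xp)[0] - m.energy(xm)[0]) / (2 * h)
        assert np.abs(num - g).max() / np.abs(g).max() < 1e-6

    def test_linear_angle_is_finite(self):
        top = Topology()
        for n, xyz in (("a", (0, 0, 0)), ("b", (1, 0, 0)), ("c", (2, 0, 0))):
            top.add_atom(Atom(id=n, element="C", coords=tuple(map(float, xyz))))
        top.add_bond("a", "b"); top.add_bond("b", "c")
        from dummycure.molgraph import AngleTerm

        top.angle_terms = [AngleTerm(("a", "b", "c"), 50.0, 109.5)]
        e, g, _ = EnergyModel(top).energy_and_gradient(top.coords_array())
        assert np.isfinite(e) and np.isfinite(g).all()

    def test_dummies_are_nonbonded_silent(self, fixture_cache):
        hyb = fixture_cache("MET2WAT").hybrids["B"].copy()
        for a in hyb.atoms.values():
            a.lj_params = (0.1, 1.2)
            a.charge = 0.1
        m = EnergyModel(hyb, nonbonded=True)
        dummies = hyb.dummy_atoms()
        ids = list(hyb.atoms)
        for i, j in m.nb_idx:
            assert ids[i] not in dummies and ids[j] not in dummies


class TestMinimize:
    def test_water_converges_to_equilibrium(self):
        top = fx.water().topology(minimize_geometry=False)
        x0 = top.coords_array()
        x0[2] += [0.2, -0.1, 0.3]  # distort
        m = EnergyModel(top)
        x, e, conv = minimize(m, x0)
        assert conv and e == pytest.approx(0.0, abs=1e-12)
        assert measure_angle(x, 1, 0, 2) == pytest.approx(109.5, abs=1e-4)

    def test_idempotent_on_minimum(self, fixture_cache):
        top = fx.methane().topology()
        m = EnergyModel(top)
        x1, e1, _ = minimize(m, top.coords_array())
        x2, e2, _ = minimize(m, x1)
        assert np.abs(x2 - x1).max() < 1e-6

    def test_nonconvergence_reports_flag(self):
        top = two_atom_bond()
        m = EnergyModel(top)
        x0 = np.array([[0, 0, 0], [2.0, 0, 0]], float)
        x, e, conv = minimize(m, x0, tol=1e-300, max_iter=1)
        assert conv in (False, True)  # returns best-so-far either way
        assert np.isfinite(e)


class TestLangevin:
    def test_same_seed_same_trajectory(self, fixture_cache):
        top = fx.water().topology()
        m = EnergyModel(top)
        t1 = langevin(m, top.coords_array(), steps=2000, seed=42)
        t2 = langevin(m, top.coords_array(), steps=2000, seed=42)
        assert np.array_equal(t1.frames, t2.frames)
        t3 = langevin(m, top.coords_array(), steps=2000, seed=43)
        assert not np.array_equal(t1.frames, t3.frames)

    def test_zero_temperature_stays_at_minimum(self):
        top = two_atom_bond()
        m = EnergyModel(top)
        traj = langevin(m, top.coords_array(), temperature=0.0, steps=2000, seed=0)
        assert np.abs(traj.frames[-1] - top.coords_array()).max() < 1e-9

    def test_equipartition_single_bond(self):
        """<k (b-b0)^2> -> kB T / 2 for one harmonic degree of freedom."""
        top = two_atom_bond()
        m = EnergyModel(top)
        traj = langevin(m, top.coords_array(), temperature=300.0, friction=5.0,
                        dt=1.0, steps=600_000, seed=7, save_interval=10)
        pot = traj.potential_energies[len(traj.potential_energies) // 10:]
        assert np.mean(pot) == pytest.approx(0.5 * KB * 300.0, rel=0.05)

    def test_nve_energy_conservation(self):
        """Symplectic sanity: friction 0, dt 0.1 fs, methane, 1e4 steps."""
        top = fx.methane().topology()
        m = EnergyModel(top)
        rng = np.random.default_rng(3)
        x0 = top.coords_array() + 0.01 * rng.standard_normal((5, 3))
        traj = langevin(m, x0, temperature=0.0, friction=0.0, dt=0.1,
                        steps=10_000, seed=0, save_interval=10)
        e_tot = traj.potential_energies + traj.kinetic_energies
        # instantaneous E oscillates within the shadow-Hamiltonian band;
        # the secular drift of its running mean is what must vanish
        n = len(e_tot) // 10
        assert np.ptp(e_tot) < 1e-3
        assert abs(e_tot[-n:].mean() - e_tot[:n].mean()) < 1e-3

    def test_bad_arguments(self):
        top = two_atom_bond()
        m = EnergyModel(top)
        with pytest.raises(ValueError):
            langevin(m, top.coords_array(), dt=0.0, steps=10, seed=0)
        with pytest.raises(ValueError):
            langevin(m, top.coords_array(), temperature=-1.0, steps=10, seed=0)

    def test_xyz_export(self, tmp_path):
        top = two_atom_bond()
        m = EnergyModel(top)
        traj = langevin(m, top.coords_array(), steps=100, seed=0, save_interval=50)
        p = tmp_path / "t.xyz"
        traj.write_xyz(p, top)
        lines = p.read_text().splitlines()
        assert lines[0] == "2" and len(lines) == 2 * 4
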