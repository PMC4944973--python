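import numpy as np
import pytest

from endstate.constants import COULOMB_K
from endstate.core import Atom, Residue, Topology
from endstate.forcefield import ParameterizationError
from endstate.gbsa import (GBSettings, SasaSettings, effective_born_radii,
                           gb_polar_energy, gb_polar_energy_pairwise,
                           lcpo_sasa, nonpolar_energy)
from endstate.params import lcpo_coefficients
from endstate.reference import (born_ion_energy, mc_descreening_integral,
                                monte_carlo_sasa)

from conftest import ion_topology


class TestBornRadii:
    def test_isolated_atom_radius_minus_offset(self):
        top = ion_topology([1.0], [1.5])
        R = effective_born_radii(top, np.zeros((1, 3)), GBSettings(offset=0.09))
        assert R[0] == pytest.approx(1.41, abs=1e-12)

    def test_distant_pair_keeps_isolated_radii(self):
        top = ion_topology([1.0, 1.0], [1.5, 1.5])
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        R = effective_born_radii(top, coords, GBSettings())
        assert np.all(np.abs(R - 1.41) < 1e-4)

    def test_overlapping_pair_against_cfa_quadrature(self):
        """HCT closed-form descreening vs Monte-Carlo CFA volume integral."""
        sep = 2.2
        top = ion_topology([1.0, 1.0], [1.5, 1.5], elements=["O", "O"])
        settings = GBSettings(screen={"O": 0.8})
        R = effective_born_radii(top, np.array([[0.0, 0, 0], [sep, 0, 0]]),
                                 settings)
        integral = mc_descreening_integral(1.41, sep, 0.8 * 1.41,
                                           n_samples=300_000, seed=1)
        R_ref = 1.0 / (1.0 / 1.41 - integral)
        assert R[0] == pytest.approx(R_ref, rel=0.10)


class TestGBPolar:
    def test_single_ion_matches_analytic_born(self):
        # intrinsic 2.09 − offset 0.09 → effective Born radius 2.0 Å
        top = ion_topology([1.0], [2.09])
        e = gb_polar_energy(top, np.zeros((1, 3)), GBSettings())
        assert e == pytest.approx(-81.98, abs=0.01)
        assert e == pytest.approx(born_ion_energy(1.0, 2.0), abs=1e-9)

    def test_zero_charges_zero_energy(self):
        top = ion_topology([0.0, 0.0], [1.5, 1.5])
        e = gb_polar_energy(top, np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        assert e == 0.0

    def test_distant_ions_match_direct_formula(self):
        top = ion_topology([1.0, 1.0], [1.5, 1.5])
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        s = GBSettings()
        R = effective_born_radii(top, coords, s)
        f = np.sqrt(2500.0 + R[0] * R[1] * np.exp(-2500.0 / (4 * R[0] * R[1])))
        pref = -0.5 * COULOMB_K * (1.0 - 1.0 / 80.0)
        direct = pref * (1.0 / R[0] + 1.0 / R[1] + 2.0 / f)
        assert gb_polar_energy(top, coords, s) == pytest.approx(direct, abs=1e-6)

    def test_charged_system_energy_is_negative(self, toy):
        topology, coords, _ = toy
        assert gb_polar_energy(topology, coords) < 0.0

    def test_rigid_motion_invariance(self, toy):
        topology, coords, _ = toy
        th = np.radians(37.0)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        moved = coords @ R.T + np.array([3.0, -11.0, 6.0])
        e1 = gb_polar_energy(topology, coords)
        e2 = gb_polar_energy(topology, moved)
        assert abs(e1 - e2) < 1e-9

    def test_pairwise_matrix_sums_to_total(self, toy):
        topology, coords, _ = toy
        m = gb_polar_energy_pairwise(topology, coords)
        assert m.sum() == pytest.approx(gb_polar_energy(topology, coords),
                                        abs=1e-9)


def _cluster(spec):
    atoms, coords = [], []
    for i, (el, rad, pos, n_nb) in enumerate(spec):
        atoms.append(Atom(serial=i + 1, name=el, element=el, residue_index=0,
                          chain_id="A", intrinsic_radius=rad,
                          lcpo_params=lcpo_coefficients(el, n_nb)))
        coords.append(pos)
    return (Topology(atoms, [Residue("X", "A:X1", 0, len(atoms))]),
            np.array(coords, float))


class TestLcpoSasa:
    def test_isolated_sphere_exact(self):
        top, coords = _cluster([("C", 1.7, (0.0, 0, 0), 0)])
        areas, total = lcpo_sasa(top, coords, SasaSettings(probe_radius=1.4))
        assert total == pytest.approx(4 * np.pi * 3.1 ** 2, abs=1e-9)
        assert total == pytest.approx(120.76, abs=0.01)

    def test_buried_atom_clamps_to_zero(self):
        # central atom caged by six tight neighbours
        spec = [("C", 1.7, (0.0, 0, 0), 4)]
        for d in ((1.6, 0, 0), (-1.6, 0, 0), (0, 1.6, 0), (0, -1.6, 0),
                  (0, 0, 1.6), (0, 0, -1.6)):
            spec.append(("C", 1.7, d, 1))
        top, coords = _cluster(spec)
        areas, _ = lcpo_sasa(top, coords)
        assert areas[0] == 0.0

    def test_hydrogens_zero_and_missing_params_raise(self, toy):
        topology, coords, _ = toy
        areas, _ = lcpo_sasa(topology, coords)
        for i, a in enumerate(topology.atoms):
            if a.element == "H":
                assert areas[i] == 0.0
        bad = ion_topology([0.0], [1.7])
        bad.atoms[0] = Atom(serial=1, name="C", element="C", residue_index=0,
                            chain_id="A", intrinsic_radius=1.7,
                            lcpo_params=None)
        with pytest.raises(ParameterizationError):
            lcpo_sasa(bad, np.zeros((1, 3)))

    @pytest.mark.parametrize("name,spec", [
        ("bent-3", [("C", 1.7, (0.0, 0, 0), 1), ("C", 1.7, (1.53, 0, 0), 2),
                    ("C", 1.7, (1.53 + 1.53 * np.cos(np.radians(70.5)),
                                1.53 * np.sin(np.radians(70.5)), 0), 1)]),
        ("star-4", [("C", 1.7, (0.0, 0, 0), 3), ("O", 1.5, (1.43, 0, 0), 1),
                    ("N", 1.55, (-0.72, 1.25, 0), 1),
                    ("C", 1.7, (-0.72, -1.25, 0), 1)]),
        ("chain-5", [("C", 1.7, (i * 1.5, 0.45 * (i % 2), 0),
                      1 if i in (0, 4) else 2) for i in range(5)]),
    ])
    def test_small_toys_against_monte_carlo(self, name, spec):
        top, coords = _cluster(spec)
        _, total = lcpo_sasa(top, coords)
        _, mc = monte_carlo_sasa(top, coords, n_samples=100_000, seed=3)
        assert total == pytest.approx(mc, rel=0.07)

    def test_additivity_at_large_separation(self, toy):
        topology, coords, cdef = toy
        rec, lig = cdef.receptor_index, cdef.ligand_index
        far = coords.copy()
        far[lig] += np.array([0.0, 100.0, 0.0])
        _, a_all = lcpo_sasa(topology, far)
        _, a_r = lcpo_sasa(topology, far, indices=rec)
        _, a_l = lcpo_sasa(topology, far, indices=lig)
        assert a_all == pytest.approx(a_r + a_l, abs=1e-6)


class TestNonpolar:
    @pytest.mark.parametrize("delta_a,gamma,beta,expected", [
        (-100.0, 0.0072, 0.0, -0.72),     # GB coefficient set
        (-100.0, 0.00542, 0.92, 0.378),   # PB coefficient set
        (0.0, 0.00542, 0.0, 0.0),
    ])
    def test_gamma_delta_a_plus_beta(self, delta_a, gamma, beta, expected):
        assert nonpolar_energy(delta_a, gamma, beta) == pytest.approx(
            expected, abs=1e-12)
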