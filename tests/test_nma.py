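import numpy as np
import pytest

from endstate.constants import C_SI, H_SI, KB_SI, KCAL_PER_MOL_A2_AMU_TO_S2, R_CAL
from endstate.core import Atom, AngleTerm, BondTerm, ComplexDefinition, \
    Residue, Topology
from endstate.forcefield import DielectricModel
from endstate.nma import (binding_entropy, entropy_from_modes,
                          minimize_snapshot, normal_modes, principal_moments,
                          rotational_entropy, species_entropy,
                          translational_entropy, vibrational_entropy,
                          ModeSpectrum)
from endstate.synthetic import ToyComplexSpec, make_toy_complex

from conftest import diatomic

VACUUM = DielectricModel.constant(1.0)


class TestMinimization:
    def test_exact_minimum_returns_unchanged(self):
        top = diatomic(k=300.0, b0=1.2)
        x = np.array([[0.0, 0, 0], [1.2, 0, 0]])
        res = minimize_snapshot(top, x, VACUUM)
        assert res.n_steps == 0
        assert np.array_equal(res.coords, x)

    def test_stretched_diatomic_relaxes_to_b0(self):
        top = diatomic(k=300.0, b0=1.2)
        res = minimize_snapshot(top, np.array([[0.0, 0, 0], [1.4, 0, 0]]), VACUUM)
        assert np.linalg.norm(res.coords[1] - res.coords[0]) == pytest.approx(
            1.2, abs=1e-4)
        assert res.converged

    def test_energy_never_increases(self, toy):
        topology, coords, _ = toy
        from endstate.forcefield import total_potential
        e0, _ = total_potential(topology, coords,
                                DielectricModel.distance_dependent(4.0))
        res = minimize_snapshot(topology, coords, max_steps=200)
        assert res.energy <= e0 + 1e-8


class TestNormalModes:
    def test_diatomic_frequency_closed_form(self):
        k, m = 300.0, 12.011
        top = diatomic(k=k, b0=1.2, mass=m)
        spec = normal_modes(top, np.array([[0.0, 0, 0], [1.2, 0, 0]]), VACUUM)
        # E = k Δr² → spring constant 2k; ω = √(2k/μ), μ = m/2
        nu_expect = np.sqrt(2 * k / (m / 2) * KCAL_PER_MOL_A2_AMU_TO_S2) \
            / (2 * np.pi * C_SI * 100.0)
        assert len(spec.frequencies) == 1
        assert spec.frequencies[0] == pytest.approx(nu_expect, rel=1e-3)
        assert spec.n_zero_modes == 5  # linear molecule

    def _triatomic(self):
        atoms = [Atom(serial=i + 1, name=f"A{i}", element="C", residue_index=0,
                      chain_id="A", mass=12.0) for i in range(3)]
        theta0 = np.radians(104.0)
        top = Topology(atoms, [Residue("TRI", "A:TRI1", 0, 3)],
                       [BondTerm(0, 1, 300.0, 1.2), BondTerm(1, 2, 300.0, 1.2)],
                       [AngleTerm(0, 1, 2, 60.0, theta0)])
        x = np.array([[1.2, 0.0, 0.0], [0.0, 0.0, 0.0],
                      [1.2 * np.cos(theta0), 1.2 * np.sin(theta0), 0.0]])
        return top, x

    def test_nonlinear_triatomic_has_six_zero_modes(self):
        top, x = self._triatomic()
        res = minimize_snapshot(top, x, VACUUM)
        spec = normal_modes(top, res.coords, VACUUM)
        assert spec.n_zero_modes == 6
        assert len(spec.frequencies) == 3 * 3 - 6
        assert not spec.warnings

    def test_mode_count_is_3n_minus_6(self):
        topology, coords, cdef = make_toy_complex(
            ToyComplexSpec(("SER",), ("PHE",), ((0, 0),)))
        rec = topology.subset(cdef.receptor_index)  # one whole serine, 6 atoms
        res = minimize_snapshot(rec, coords[cdef.receptor_index],
                                max_steps=5000, grms_tol=1e-5)
        spec = normal_modes(rec, res.coords)
        assert spec.n_zero_modes == 6
        assert len(spec.frequencies) == 3 * rec.n_atoms - 6
        assert not spec.warnings


class TestEntropyFormulas:
    def test_frozen_mode_limit(self):
        assert vibrational_entropy(np.array([1e7]), 300.0) < 1e-12

    def test_single_mode_closed_form(self):
        nu, T = 208.5, 300.0
        theta = H_SI * C_SI * 100.0 * nu / KB_SI
        x = theta / T
        expected = R_CAL * (x / (np.exp(x) - 1.0) - np.log(1.0 - np.exp(-x)))
        assert vibrational_entropy(np.array([nu]), T) == pytest.approx(
            expected, abs=1e-12)

    def test_vibrational_entropy_monotonic_in_frequency(self):
        freqs = np.linspace(20.0, 3000.0, 40)
        s = [vibrational_entropy(np.array([f]), 300.0) for f in freqs]
        assert np.all(np.diff(s) < 0)

    def test_mass_doubling_raises_s_trans_by_3half_r_ln2(self):
        d = translational_entropy(200.0, 300.0) - translational_entropy(100.0, 300.0)
        assert d == pytest.approx(1.5 * R_CAL * np.log(2.0), abs=1e-9)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            vibrational_entropy(np.array([-5.0]), 300.0)
        spec = ModeSpectrum(np.array([]), 6)
        res = entropy_from_modes(spec, 100.0, np.array([10.0, 20.0, 30.0]), 300.0)
        assert res.s_vib == 0.0
        assert res.s_total == pytest.approx(res.s_trans + res.s_rot, abs=1e-12)


@pytest.fixture(scope="module")
def dimer():
    return make_toy_complex(ToyComplexSpec(("SER",), ("PHE",), ((0, 0),)))


class TestBindingEntropy:
    def test_separated_species_have_additive_vibrational_entropy(self, dimer):
        topology, coords, cdef = dimer
        far = coords.copy()
        far[cdef.ligand_index] += np.array([0.0, 120.0, 0.0])
        ent_c, _ = species_entropy(topology, far, max_steps=3000)
        rec = topology.subset(cdef.receptor_index)
        lig = topology.subset(cdef.ligand_index)
        ent_r, _ = species_entropy(rec, far[cdef.receptor_index], max_steps=3000)
        ent_l, _ = species_entropy(lig, far[cdef.ligand_index], max_steps=3000)
        # no interface contacts → ΔS_vib ≈ 0 (rigid-body association terms remain)
        assert ent_c.s_vib == pytest.approx(ent_r.s_vib + ent_l.s_vib, abs=0.05)

    def test_single_snapshot_se_zero_with_flag(self, dimer):
        topology, coords, cdef = dimer
        res = binding_entropy([coords], topology, cdef, max_steps=2000)
        assert res.se == 0.0
        assert res.single_snapshot
        assert res.minus_t_delta_s > 0  # association loses entropy

    def test_mean_is_per_snapshot_average(self, dimer):
        topology, coords, cdef = dimer
        rng = np.random.default_rng(11)
        snaps = [coords + rng.normal(0, 0.01, coords.shape) for _ in range(3)]
        res = binding_entropy(snaps, topology, cdef, max_steps=2000)
        assert res.minus_t_delta_s == pytest.approx(res.per_snapshot.mean(),
                                                    abs=1e-12)
        assert not res.single_snapshot

    def test_rotation_invariance_of_entropy(self, dimer):
        topology, coords, cdef = dimer
        th = np.radians(23.0)
        R = np.array([[1, 0, 0], [0, np.cos(th), -np.sin(th)],
                      [0, np.sin(th), np.cos(th)]])
        e1, _ = species_entropy(topology, coords, max_steps=3000)
        e2, _ = species_entropy(topology, coords @ R.T, max_steps=3000)
        assert e1.s_total == pytest.approx(e2.s_total, abs=1e-6)


class TestInertia:
    def test_principal_moments_of_known_rotor(self):
        # two masses m at ±d/2 on x: I = (m d²/2, m d²/2, 0)
        coords = np.array([[0.6, 0, 0], [-0.6, 0, 0]])
        m = np.array([12.0, 12.0])
        I = principal_moments(coords, m)
        assert I[0] == pytest.approx(0.0, abs=1e-12)
        assert I[2] == pytest.approx(2 * 12.0 * 0.36, abs=1e-9)
        # linear-molecule branch of the rotational entropy
        s = rotational_entropy(I, 300.0)
        assert np.isfinite(s) and s > 0
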