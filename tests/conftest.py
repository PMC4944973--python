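import numpy as np
import pytest

from endstate.core import Atom, BondTerm, Residue, Topology
from endstate.synthetic import (FluctuationSpec, ToyComplexSpec,
                                make_toy_complex, make_trajectory)

STANDARD_SPEC = ToyComplexSpec(("LYS", "SER", "ALA"), ("ASP", "PHE", "GLY"),
                               ((1, 1), (0, 0)))


@pytest.fixture(scope="session")
def toy():
    """Standard toy dimer: salt bridge (LYS/ASP) + OH-π pair (SER/PHE)."""
    topology, coords, cdef = make_toy_complex(STANDARD_SPEC)
    return topology, coords, cdef


@pytest.fixture(scope="session")
def toy_traj(toy):
    topology, coords, _ = toy
    return make_trajectory(topology, coords, FluctuationSpec(
        n_frames=50, dt_ps=10.0, isotropic_sigma=0.06, seed=7))


def ion_topology(charges, radii, elements=None, names=None):
    """n free ions in one residue (no bonds) for solvation tests."""
    n = len(charges)
    elements = elements or ["C"] * n
    atoms = [Atom(serial=i + 1, name=(names[i] if names else f"X{i}"),
                  element=elements[i], residue_index=0, chain_id="A",
                  charge=charges[i], intrinsic_radius=radii[i],
                  lcpo_params=(1.0, 0.0, 0.0, 0.0))
             for i in range(n)]
    return Topology(atoms, [Residue("ION", "A:ION1", 0, n)])


def diatomic(k=300.0, b0=1.2, mass=12.011, charge=0.0):
    atoms = [Atom(serial=i + 1, name=f"C{i}", element="C", residue_index=0,
                  chain_id="A", mass=mass, charge=charge) for i in range(2)]
    return Topology(atoms, [Residue("DIA", "A:DIA1", 0, 2)],
                    [BondTerm(0, 1, k, b0)])
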