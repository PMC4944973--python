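"""Independent numerical references for validating the fast approximations.

These routines deliberately share no code with the production paths: SASA
by rejection sampling on probe-augmented spheres, the GB descreening
integral by Monte-Carlo volume quadrature of the Coulomb-field
approximation, the Born ion in closed form, and the Kirkwood multipole
series for charges inside a dielectric sphere.  They are slow and exist to
quantify the error of LCPO, pairwise GB and the finite-difference PB solver
on small systems.
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre

from .constants import COULOMB_K
from .core import Topology


def monte_carlo_sasa(topology: Topology, coords: np.ndarray, probe: float = 1.4,
                     n_samples: int = 100_000, seed: int = 0,
                     indices=None) -> tuple[np.ndarray, float]:
    """Per-atom and total SASA by uniform sampling on each sphere.

    Heavy atoms only (hydrogens carry no area, matching the LCPO
    convention).
    """
    idx = np.arange(topology.n_atoms) if indices is None else np.asarray(sorted(indices), int)
    rng = np.random.default_rng(seed)
    x = np.asarray(coords, float)[idx]
    heavy = np.array([topology.atoms[i].element != "H" for i in idx])
    R = np.array([topology.atoms[i].intrinsic_radius + probe for i in idx])
    areas = np.zeros(len(idx))
    for a in np.nonzero(heavy)[0]:
        pts = rng.normal(size=(n_samples, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = x[a] + R[a] * pts
        exposed = np.ones(n_samples, dtype=bool)
        for b in np.nonzero(heavy)[0]:
            if b == a:
                continue
            d2 = np.sum((pts - x[b]) ** 2, axis=1)
            exposed &= d2 > R[b] ** 2
        areas[a] = 4.0 * np.pi * R[a] ** 2 * exposed.mean()
    return areas, float(areas.sum())


def mc_descreening_integral(rho_i: float, separation: float, neighbor_radius: float,
                            n_samples: int = 200_000, seed: int = 0) -> float:
    """Coulomb-field-approximation descreening integral, by MC quadrature.

    I = (1/4π) ∫ dV / r⁴ over the neighbour sphere (radius
    ``neighbor_radius`` centred ``separation`` away), excluding any part
    inside the atom's own sphere ``rho_i``; 1/R_eff = 1/ρ_i − I.
    """
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-1.0, 1.0, size=(n_samples, 3))
    inside = np.sum(pts * pts, axis=1) <= 1.0
    pts = pts[inside] * neighbor_radius
    pts[:, 0] += separation
    r2 = np.sum(pts * pts, axis=1)
    keep = r2 > rho_i * rho_i
    vol = 4.0 / 3.0 * np.pi * neighbor_radius ** 3
    integrand = np.zeros(len(pts))
    integrand[keep] = 1.0 / r2[keep] ** 2
    return float(integrand.mean() * vol / (4.0 * np.pi))


def born_ion_energy(q: float, radius: float, eps_in: float = 1.0,
                    eps_out: float = 80.0) -> float:
    """Closed-form Born solvation energy, kcal/mol."""
    return -COULOMB_K * q * q / (2.0 * radius) * (1.0 / eps_in - 1.0 / eps_out)


def kirkwood_energy(charges: np.ndarray, positions: np.ndarray, sphere_radius: float,
                    eps_in: float = 1.0, eps_out: float = 80.0,
                    l_max: int = 40) -> float:
    """Kirkwood series reaction-field energy for charges in a sphere, kcal/mol.

    ΔG = −(k/2) Σ_l B_l Σ_ij q_i q_j r_i^l r_j^l P_l(cos γ_ij) / a^{2l+1},
    B_l = (l+1)(ε_out − ε_in) / (ε_in [(l+1)ε_out + l ε_in]).
    """
    q = np.asarray(charges, float)
    x = np.asarray(positions, float)
    r = np.linalg.norm(x, axis=1)
    if np.any(r >= sphere_radius):
        raise ValueError("all charges must lie inside the sphere")
    unit = np.where(r[:, None] > 0, x / np.maximum(r, 1e-300)[:, None], 0.0)
    cosg = np.clip(unit @ unit.T, -1.0, 1.0)
    cosg[(r[:, None] == 0) | (r[None, :] == 0)] = 1.0
    total = 0.0
    for l in range(l_max + 1):
        B = (l + 1) * (eps_out - eps_in) / (eps_in * ((l + 1) * eps_out + l * eps_in))
        rl = r ** l
        total += B / sphere_radius ** (2 * l + 1) * float(
            np.sum(np.outer(q * rl, q * rl) * eval_legendre(l, cosg)))
    return -0.5 * COULOMB_K * total
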