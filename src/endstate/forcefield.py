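"""Molecular-mechanics energy terms, gradient and Hessian.

Conventions (Amber style, stated once here and relied on everywhere):

* Coulomb constant k = 332.0637 kcal·Å/(mol·e²).
* Harmonic bonds and angles carry **no** factor ½:  E = k (r − b0)²,
  E = k (θ − θ0)².
* Dihedrals are a cosine series, E = (V/2)(1 + cos(nφ − γ)); ``v_half``
  stores V/2 directly.
* The distance-dependent dielectric model means ε(r) = ε·r, so the pair
  energy is k q_i q_j / (ε r²) — the form used by gas-phase minimization
  protocols (ε = 4 gives the classic "4r(i,j)" dielectric).
* Nonbonded pairs separated by one or two bonds are excluded; 1-4 pairs are
  scaled (defaults: electrostatics × 1/1.2, van der Waals × 1/2).
* No cutoffs: end-state energies sum over all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import COULOMB_K
from .core import Topology

SCEE_DEFAULT = 1.0 / 1.2
SCNB_DEFAULT = 0.5


class SingularityError(ValueError):
    """Coincident atoms where a pair distance must be positive."""


class ParameterizationError(KeyError):
    """A bonded or per-atom parameter required by the potential is missing."""


@dataclass(frozen=True)
class DielectricModel:
    """Constant (ε) or distance-dependent (ε·r) dielectric."""

    kind: str  # "constant" | "distance_dependent"
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.kind not in ("constant", "distance_dependent"):
            raise ValueError(f"unknown dielectric kind {self.kind!r}")

    @staticmethod
    def constant(epsilon: float = 1.0) -> "DielectricModel":
        return DielectricModel("constant", epsilon)

    @staticmethod
    def distance_dependent(epsilon: float = 4.0) -> "DielectricModel":
        return DielectricModel("distance_dependent", epsilon)


def _pair_distances(coords: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    d = coords[ia][:, None, :] - coords[ib][None, :, :]
    return np.sqrt(np.sum(d * d, axis=-1))


def coulomb_energy(topology: Topology, coords: np.ndarray,
                   atoms_a: Sequence[int], atoms_b: Sequence[int],
                   model: DielectricModel = DielectricModel.constant(1.0)) -> float:
    """Intergroup Coulomb energy (kcal/mol) between disjoint atom sets."""
    ia = np.asarray(list(atoms_a), dtype=int)
    ib = np.asarray(list(atoms_b), dtype=int)
    if np.intersect1d(ia, ib).size:
        raise ValueError("atom sets must be disjoint")
    q = topology.charges
    r = _pair_distances(np.asarray(coords, float), ia, ib)
    if np.any(r <= 0):
        raise SingularityError("coincident atoms across the two sets")
    qq = np.outer(q[ia], q[ib])
    if model.kind == "constant":
        return float(COULOMB_K * np.sum(qq / (model.epsilon * r)))
    return float(COULOMB_K * np.sum(qq / (model.epsilon * r * r)))


def lj_energy(topology: Topology, coords: np.ndarray,
              atoms_a: Sequence[int], atoms_b: Sequence[int]) -> float:
    """Intergroup 12-6 Lennard-Jones energy with Lorentz–Berthelot combination."""
    ia = np.asarray(list(atoms_a), dtype=int)
    ib = np.asarray(list(atoms_b), dtype=int)
    if np.intersect1d(ia, ib).size:
        raise ValueError("atom sets must be disjoint")
    r = _pair_distances(np.asarray(coords, float), ia, ib)
    if np.any(r <= 0):
        raise SingularityError("coincident atoms across the two sets")
    rh, ep = topology.lj_rmin_half, topology.lj_epsilon
    rmin = rh[ia][:, None] + rh[ib][None, :]
    eps = np.sqrt(np.outer(ep[ia], ep[ib]))
    s6 = (rmin / r) ** 6
    return float(np.sum(eps * (s6 * s6 - 2.0 * s6)))


# ---------------------------------------------------------------------------
# full potential: bonded + intra nonbonded with exclusions
# ---------------------------------------------------------------------------

def exclusion_maps(topology: Topology) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """(excluded 1-2/1-3 pairs, scaled 1-4 pairs), each as sorted index tuples.

    A pair bonded through ≤2 bonds is excluded; through exactly 3 bonds it is
    scaled, unless it is also reachable in ≤2 (rings).
    """
    n = topology.n_atoms
    adj: list[set[int]] = [set() for _ in range(n)]
    for b in topology.bonds:
        adj[b.i].add(b.j)
        adj[b.j].add(b.i)
    excluded: set[tuple[int, int]] = set()
    scaled: set[tuple[int, int]] = set()
    for i in range(n):
        one = adj[i]
        two = set().union(*(adj[j] for j in one)) if one else set()
        three = set().union(*(adj[j] for j in two)) if two else set()
        for j in (one | two) - {i}:
            excluded.add((min(i, j), max(i, j)))
        for j in three - one - two - {i}:
            scaled.add((min(i, j), max(i, j)))
    scaled -= excluded
    return excluded, scaled


def _nonbonded_pair_tables(topology: Topology):
    """Precompute (i, j, qq, rmin, eps, ele_scale, vdw_scale) arrays for all
    non-excluded intramolecular pairs."""
    n = topology.n_atoms
    excluded, scaled = exclusion_maps(topology)
    ii, jj = np.triu_indices(n, k=1)
    keep = np.array([(a, b) not in excluded for a, b in zip(ii, jj)], dtype=bool)
    if n < 2:
        keep = np.zeros(0, dtype=bool)
    ii, jj = ii[keep], jj[keep]
    is14 = np.array([(a, b) in scaled for a, b in zip(ii, jj)], dtype=bool)
    return ii, jj, is14


def total_potential(topology: Topology, coords: np.ndarray,
                    model: DielectricModel = DielectricModel.constant(1.0),
                    scee: float = SCEE_DEFAULT, scnb: float = SCNB_DEFAULT
                    ) -> tuple[float, np.ndarray]:
    """Full potential energy (kcal/mol) and its analytic gradient (kcal/mol/Å).

    Terms: harmonic bonds/angles, cosine dihedrals, and non-excluded
    intramolecular Coulomb + Lennard-Jones with 1-4 scaling.
    """
    x = np.asarray(coords, dtype=float)
    if x.shape != (topology.n_atoms, 3):
        raise ValueError("coords must be (n_atoms, 3)")
    energy = 0.0
    grad = np.zeros_like(x)

    # bonds
    for b in topology.bonds:
        d = x[b.i] - x[b.j]
        r = float(np.linalg.norm(d))
        if r == 0.0:
            raise SingularityError(f"bond ({b.i},{b.j}) has zero length")
        energy += b.k * (r - b.b0) ** 2
        g = 2.0 * b.k * (r - b.b0) * d / r
        grad[b.i] += g
        grad[b.j] -= g

    # angles
    for a in topology.angles:
        u = x[a.i] - x[a.j]
        v = x[a.k] - x[a.j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        ct = float(np.dot(u, v) / (nu * nv))
        ct = min(1.0, max(-1.0, ct))
        theta = np.arccos(ct)
        st = np.sqrt(max(1.0 - ct * ct, 1e-12))
        energy += a.force_k * (theta - a.theta0) ** 2
        dEdtheta = 2.0 * a.force_k * (theta - a.theta0)
        # dθ/du = −(v̂ − cosθ·û)/(|u| sinθ)
        gi = -dEdtheta * (v / nv - ct * u / nu) / (nu * st)
        gk = -dEdtheta * (u / nu - ct * v / nv) / (nv * st)
        grad[a.i] += gi
        grad[a.k] += gk
        grad[a.j] -= gi + gk

    # dihedrals
    for d in topology.dihedrals:
        b1 = x[d.j] - x[d.i]
        b2 = x[d.k] - x[d.j]
        b3 = x[d.l] - x[d.k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2)
        n1sq = float(np.dot(n1, n1))
        n2sq = float(np.dot(n2, n2))
        if n1sq < 1e-18 or n2sq < 1e-18 or nb2 < 1e-9:
            continue  # colinear: dihedral undefined, torque-free
        phi = float(np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2)))
        energy += d.v_half * (1.0 + np.cos(d.n * phi - d.gamma))
        dEdphi = -d.v_half * d.n * np.sin(d.n * phi - d.gamma)
        dphi_di = -nb2 / n1sq * n1
        dphi_dl = nb2 / n2sq * n2
        c12 = float(np.dot(b1, b2)) / (nb2 * nb2)
        c32 = float(np.dot(b3, b2)) / (nb2 * nb2)
        dphi_dj = (-c12 - 1.0) * dphi_di + c32 * dphi_dl
        dphi_dk = -(dphi_di + dphi_dj + dphi_dl)  # translation invariance
        grad[d.i] += dEdphi * dphi_di
        grad[d.j] += dEdphi * dphi_dj
        grad[d.k] += dEdphi * dphi_dk
        grad[d.l] += dEdphi * dphi_dl

    # nonbonded (vectorized over pairs)
    ii, jj, is14 = _nonbonded_pair_tables(topology)
    if len(ii):
        dv = x[ii] - x[jj]
        r = np.sqrt(np.sum(dv * dv, axis=1))
        if np.any(r <= 0):
            raise SingularityError("coincident nonbonded atoms")
        q = topology.charges
        qq = q[ii] * q[jj]
        e_scale = np.where(is14, scee, 1.0)
        v_scale = np.where(is14, scnb, 1.0)
        if model.kind == "constant":
            e_ele = COULOMB_K * qq / (model.epsilon * r)
            de_dr = -e_ele / r
        else:
            e_ele = COULOMB_K * qq / (model.epsilon * r * r)
            de_dr = -2.0 * e_ele / r
        rh, ep = topology.lj_rmin_half, topology.lj_epsilon
        rmin = rh[ii] + rh[jj]
        eps = np.sqrt(ep[ii] * ep[jj])
        s6 = (rmin / r) ** 6
        e_lj = eps * (s6 * s6 - 2.0 * s6)
        dlj_dr = -12.0 * eps * (s6 * s6 - s6) / r
        energy += float(np.sum(e_scale * e_ele) + np.sum(v_scale * e_lj))
        dr = (e_scale * de_dr + v_scale * dlj_dr) / r
        pair_g = dv * dr[:, None]
        np.add.at(grad, ii, pair_g)
        np.add.at(grad, jj, -pair_g)

    return float(energy), grad


def hessian(topology: Topology, coords: np.ndarray,
            model: DielectricModel = DielectricModel.constant(1.0),
            step: float = 1e-5, **kwargs) -> np.ndarray:
    """Mass-unweighted 3N×3N second-derivative matrix of :func:`total_potential`.

    Computed by central differences of the analytic gradient and symmetrized;
    for the harmonic terms the gradient is (piecewise) smooth so the result
    is accurate to O(step²).
    """
    x = np.asarray(coords, dtype=float).copy()
    n3 = x.size
    H = np.empty((n3, n3))
    flat = x.reshape(-1)
    for a in range(n3):
        orig = flat[a]
        flat[a] = orig + step
        _, gp = total_potential(topology, x, model, **kwargs)
        flat[a] = orig - step
        _, gm = total_potential(topology, x, model, **kwargs)
        flat[a] = orig
        H[a] = (gp - gm).reshape(-1) / (2.0 * step)
    return 0.5 * (H + H.T)
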