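"""Generalized-Born polar solvation and LCPO solvent-accessible surface area.

The GB branch is a pairwise-descreening ("HCT"-type) model: each atom's
effective Born radius starts from its intrinsic radius minus a fixed offset
and is reduced by the Coulomb-field-approximation integral over every
neighbouring sphere (scaled by a per-element descreening factor).  The polar
energy then follows Still's combining function

    ΔG_pol = −½ k (1/ε_in − 1/ε_out) Σ_ij q_i q_j / f_GB(r_ij, R_i, R_j)
    f_GB   = sqrt(r² + R_i R_j exp(−r² / (4 R_i R_j)))

with the i = j "self" terms included (f_GB = R_i), which for an isolated ion
reduces to the analytic Born formula.

The nonpolar term is ΔG_SA = γ·ΔA + β over the LCPO (Linear Combination of
Pairwise Overlaps) approximation to the solvent-accessible surface area.
Hydrogens carry zero LCPO area; heavy atoms use four coefficients P1..P4
keyed by element and bonded-heavy-neighbour count from a replaceable table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import COULOMB_K
from .core import Topology
from .forcefield import ParameterizationError

# per-element HCT descreening scale factors (dimensionless)
DEFAULT_SCREEN = {"H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85, "S": 0.96, "P": 0.86}


@dataclass(frozen=True)
class GBSettings:
    """Generalized-Born model settings.

    ``offset`` (Å) is subtracted from every intrinsic radius before
    descreening; ``screen`` maps element → descreening scale.
    """

    solute_dielectric: int = 1
    solvent_dielectric: float = 80.0
    offset: float = 0.09
    screen: dict = field(default_factory=lambda: dict(DEFAULT_SCREEN))

    def __post_init__(self) -> None:
        if self.solute_dielectric not in (1, 2, 4):
            raise ValueError("solute_dielectric must be 1, 2 or 4")
        if not self.solvent_dielectric > self.solute_dielectric:
            raise ValueError("solvent dielectric must exceed solute dielectric")


@dataclass(frozen=True)
class SasaSettings:
    """LCPO / nonpolar-term settings: probe radius and γ·ΔA + β coefficients."""

    probe_radius: float = 1.4
    gamma: float = 0.0072  # kcal/mol/Å² (GB convention)
    beta: float = 0.0  # kcal/mol

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")


# GB / PB coefficient pairs used by the two solvent models
GB_SASA = SasaSettings(gamma=0.0072, beta=0.0)
PB_SASA = SasaSettings(gamma=0.00542, beta=0.92)


def _subset(topology: Topology, indices) -> np.ndarray:
    if indices is None:
        return np.arange(topology.n_atoms)
    return np.asarray(sorted(indices), dtype=int)


def effective_born_radii(topology: Topology, coords: np.ndarray,
                         settings: GBSettings = GBSettings(),
                         indices: Sequence[int] | None = None) -> np.ndarray:
    """Per-atom effective Born radii (Å) for the atoms in ``indices``.

    Pairwise HCT descreening: 1/R_i = 1/ρ_i − I_i with ρ_i the offset-reduced
    intrinsic radius and I_i the sum of analytic sphere integrals over all
    other atoms in the same species.  An isolated atom's effective radius is
    exactly ρ_i.
    """
    idx = _subset(topology, indices)
    x = np.asarray(coords, float)[idx]
    rad = topology.radii[idx]
    rho = rad - settings.offset
    if np.any(rho <= 0):
        raise ValueError("offset-reduced radius must stay positive")
    scale = np.array([settings.screen.get(topology.atoms[i].element, 0.8) for i in idx])
    n = len(idx)
    inv = 1.0 / rho
    for a in range(n):
        integral = 0.0
        for b in range(n):
            if a == b:
                continue
            r = float(np.linalg.norm(x[a] - x[b]))
            if r == 0.0:
                raise FloatingPointError(f"coincident atoms {idx[a]} and {idx[b]}")
            sj = scale[b] * rho[b]
            U = r + sj
            if rho[a] >= U:
                continue  # neighbour fully inside atom a
            L = max(rho[a], abs(r - sj))
            term = (1.0 / L - 1.0 / U
                    + (r / 4.0) * (1.0 / U ** 2 - 1.0 / L ** 2)
                    + (1.0 / (2.0 * r)) * np.log(L / U)
                    + (sj * sj / (4.0 * r)) * (1.0 / L ** 2 - 1.0 / U ** 2))
            integral += 0.5 * term
        inv[a] = 1.0 / rho[a] - integral
    if np.any(inv <= 0):
        raise FloatingPointError("descreening exceeded the intrinsic radius bound")
    return 1.0 / inv


def gb_polar_energy(topology: Topology, coords: np.ndarray,
                    settings: GBSettings = GBSettings(),
                    indices: Sequence[int] | None = None,
                    born_radii: np.ndarray | None = None) -> float:
    """Still-style pairwise GB polar solvation energy (kcal/mol)."""
    idx = _subset(topology, indices)
    x = np.asarray(coords, float)[idx]
    q = topology.charges[idx]
    R = effective_born_radii(topology, coords, settings, idx) \
        if born_radii is None else np.asarray(born_radii, float)
    d = x[:, None, :] - x[None, :, :]
    r2 = np.sum(d * d, axis=-1)
    RR = np.outer(R, R)
    f = np.sqrt(r2 + RR * np.exp(-r2 / (4.0 * RR)))
    pref = -0.5 * COULOMB_K * (1.0 / settings.solute_dielectric
                               - 1.0 / settings.solvent_dielectric)
    return float(pref * np.sum(np.outer(q, q) / f))


def gb_polar_energy_pairwise(topology: Topology, coords: np.ndarray,
                             settings: GBSettings = GBSettings(),
                             indices: Sequence[int] | None = None) -> np.ndarray:
    """Matrix of per-pair GB contributions (diagonal = self terms).

    ``result.sum()`` equals :func:`gb_polar_energy`; used by the per-residue
    decomposition, which splits each off-diagonal entry ½:½ between the two
    atoms' residues.
    """
    idx = _subset(topology, indices)
    x = np.asarray(coords, float)[idx]
    q = topology.charges[idx]
    R = effective_born_radii(topology, coords, settings, idx)
    d = x[:, None, :] - x[None, :, :]
    r2 = np.sum(d * d, axis=-1)
    RR = np.outer(R, R)
    f = np.sqrt(r2 + RR * np.exp(-r2 / (4.0 * RR)))
    pref = -0.5 * COULOMB_K * (1.0 / settings.solute_dielectric
                               - 1.0 / settings.solvent_dielectric)
    return pref * np.outer(q, q) / f


# ---------------------------------------------------------------------------
# LCPO SASA
# ---------------------------------------------------------------------------

def _overlap_area(Ri: float, Rj: float, r: float) -> float:
    """Area of sphere i buried inside sphere j (both probe-augmented radii)."""
    if r >= Ri + Rj:
        return 0.0
    if r + Ri <= Rj:
        return 4.0 * np.pi * Ri * Ri  # i fully inside j
    if r + Rj <= Ri:
        return 0.0  # j fully inside i: nothing of i's surface buried
    return 2.0 * np.pi * Ri * (Ri - r / 2.0 - (Ri * Ri - Rj * Rj) / (2.0 * r))


def lcpo_sasa(topology: Topology, coords: np.ndarray,
              settings: SasaSettings = SasaSettings(),
              indices: Sequence[int] | None = None) -> tuple[np.ndarray, float]:
    """LCPO per-atom solvent-accessible areas (Å²) and their total.

    A_i = P1·S1 + P2·Σ_j A_ij + P3·Σ_{j<k∈N(i)} A_jk
        + P4·Σ_j A_ij Σ_{k∈N(i)∩N(j)} A_jk,
    with S1 the isolated probe-augmented sphere area, A_ij the area of
    sphere i buried by sphere j and N(i) the set of geometrically
    overlapping neighbours.  Hydrogens get zero area; per-atom areas are
    clamped at ≥ 0.
    """
    idx = _subset(topology, indices)
    x = np.asarray(coords, float)[idx]
    n = len(idx)
    R = np.array([topology.atoms[i].intrinsic_radius + settings.probe_radius
                  for i in idx])
    heavy = np.array([topology.atoms[i].element != "H" for i in idx])
    missing = [int(i) for i in idx
               if topology.atoms[i].element != "H"
               and topology.atoms[i].lcpo_params is None]
    if missing:
        raise ParameterizationError(f"missing LCPO parameters for heavy atoms {missing}")
    P = np.array([topology.atoms[i].lcpo_params or (0.0,) * 4 for i in idx])

    dist = np.sqrt(np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1))
    areas = np.zeros(n)
    # neighbour lists over heavy atoms only (hydrogens do not occlude in LCPO)
    neigh: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        if not heavy[i]:
            continue
        for j in range(n):
            if j != i and heavy[j] and dist[i, j] < R[i] + R[j]:
                neigh[i].append(j)

    for i in range(n):
        if not heavy[i]:
            continue
        p1, p2, p3, p4 = P[i]
        s1 = 4.0 * np.pi * R[i] * R[i]
        sum_aij = 0.0
        sum_ajk = 0.0
        sum_mixed = 0.0
        for j in neigh[i]:
            aij = _overlap_area(R[i], R[j], dist[i, j])
            sum_aij += aij
            inner = 0.0
            for k in neigh[i]:
                if k != j and dist[j, k] < R[j] + R[k]:
                    inner += _overlap_area(R[j], R[k], dist[j, k])
            sum_mixed += aij * inner
        for a_pos in range(len(neigh[i])):
            for b_pos in range(a_pos + 1, len(neigh[i])):
                j, k = neigh[i][a_pos], neigh[i][b_pos]
                if dist[j, k] < R[j] + R[k]:
                    sum_ajk += _overlap_area(R[j], R[k], dist[j, k])
        areas[i] = max(0.0, p1 * s1 + p2 * sum_aij + p3 * sum_ajk + p4 * sum_mixed)
    return areas, float(np.sum(areas))


def nonpolar_energy(delta_area: float, gamma: float, beta: float) -> float:
    """ΔG_SA = γ·ΔA + β (kcal/mol)."""
    return gamma * delta_area + beta
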