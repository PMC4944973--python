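"""Finite-difference linearized Poisson–Boltzmann polar solvation.

Solves ∇·ε∇φ = −4πρ (zero ionic strength) on a uniform cubic grid with a
7-point stencil.  The dielectric is defined on grid *edges*: an edge takes
the harmonic mean of solute and solvent dielectric weighted by the fraction
of the edge inside the van der Waals surface (intrinsic radii, no probe).
Charges are spread to the eight surrounding nodes with trilinear weights;
the Dirichlet boundary condition is the Coulomb monopole potential screened
by the solvent dielectric (Debye–Hückel at zero salt).

The polar solvation energy uses a two-solve reference scheme:
ΔG_PB = ½ Σ q_i [φ(ε_out) − φ(ε_out = ε_in)](r_i), which cancels the grid
self-energy exactly because both solves share the same grid and charge
spreading.

Potentials are returned in kcal/mol/e; energies in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import cg

from .constants import COULOMB_K
from .core import Topology


class PBSolverError(RuntimeError):
    """Iterative solve failed to reach the residual tolerance."""


@dataclass(frozen=True)
class PBGrid:
    """Uniform cubic grid specification for the finite-difference solve."""

    spacing: float = 0.5  # Å
    margin: float = 8.0  # Å of solvent beyond every solute sphere
    tolerance: float = 1e-6  # relative residual
    max_iterations: int = 20000
    edge_samples: int = 7  # points per edge for the inside-fraction estimate

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.margin < 8.0:
            raise ValueError("solute must be enclosed with >= 8 Å margin")


def _grid_axes(coords: np.ndarray, radii: np.ndarray, grid: PBGrid):
    lo = np.min(coords - radii[:, None], axis=0) - grid.margin
    hi = np.max(coords + radii[:, None], axis=0) + grid.margin
    h = grid.spacing
    ns = np.ceil((hi - lo) / h).astype(int) + 1
    # pad symmetrically so the box is centred on the solute bounding box
    pad = (ns - 1) * h - (hi - lo)
    axes = [lo[d] - pad[d] / 2.0 + h * np.arange(ns[d]) for d in range(3)]
    return axes, ns


def _inside_fraction(points: np.ndarray, coords: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Fraction helper: boolean inside-any-sphere for a flat point array."""
    inside = np.zeros(len(points), dtype=bool)
    for c, r in zip(coords, radii):
        d2 = np.sum((points - c) ** 2, axis=1)
        inside |= d2 <= r * r
    return inside


def _edge_dielectric(axes, ns, coords, radii, eps_in, eps_out, grid: PBGrid):
    """Edge-centred dielectric arrays (ex, ey, ez) via fractional harmonic mean."""
    h = grid.spacing
    ts = (np.arange(grid.edge_samples) + 0.5) / grid.edge_samples
    out = []
    for d in range(3):
        shape = [ns[0], ns[1], ns[2]]
        shape[d] -= 1
        X, Y, Z = np.meshgrid(axes[0][: shape[0]], axes[1][: shape[1]],
                              axes[2][: shape[2]], indexing="ij")
        base = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
        frac = np.zeros(len(base))
        step = np.zeros(3)
        step[d] = h
        for t in ts:
            frac += _inside_fraction(base + t * step, coords, radii)
        frac /= grid.edge_samples
        eps = 1.0 / (frac / eps_in + (1.0 - frac) / eps_out)
        out.append(eps.reshape(shape))
    return out


def _spread_charges(axes, ns, coords, charges):
    """Trilinear charge-to-node spreading; returns the dense node-charge grid."""
    h = axes[0][1] - axes[0][0]
    q_grid = np.zeros(tuple(ns))
    for pos, q in zip(coords, charges):
        f = [(pos[d] - axes[d][0]) / h for d in range(3)]
        i0 = [int(np.floor(f[d])) for d in range(3)]
        w = [f[d] - i0[d] for d in range(3)]
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wt = ((w[0] if dx else 1 - w[0])
                          * (w[1] if dy else 1 - w[1])
                          * (w[2] if dz else 1 - w[2]))
                    q_grid[i0[0] + dx, i0[1] + dy, i0[2] + dz] += q * wt
    return q_grid


def _boundary_potential(axes, ns, coords, charges, eps):
    """Coulomb monopole-sum Dirichlet values on the six box faces (reduced units)."""
    phi = np.zeros(tuple(ns))
    X, Y, Z = np.meshgrid(axes[0], axes[1], axes[2], indexing="ij")
    mask = np.zeros(tuple(ns), dtype=bool)
    mask[0, :, :] = mask[-1, :, :] = True
    mask[:, 0, :] = mask[:, -1, :] = True
    mask[:, :, 0] = mask[:, :, -1] = True
    pts = np.stack([X[mask], Y[mask], Z[mask]], axis=-1)
    vals = np.zeros(len(pts))
    for c, q in zip(coords, charges):
        r = np.sqrt(np.sum((pts - c) ** 2, axis=1))
        vals += q / (eps * np.maximum(r, 1e-9))
    phi[mask] = vals
    return phi, mask


def solve_pb(topology: Topology, coords: np.ndarray, eps_in: float, eps_out: float,
             grid: PBGrid = PBGrid(), indices=None) -> tuple[np.ndarray, list[np.ndarray]]:
    """Solve the linearized PB equation; returns (node potentials, axes).

    Potentials are in kcal/mol/e on the full grid (Dirichlet shell included).
    """
    idx = np.arange(topology.n_atoms) if indices is None else np.asarray(sorted(indices), int)
    x = np.asarray(coords, float)[idx]
    q = topology.charges[idx]
    radii = topology.radii[idx]
    axes, ns = _grid_axes(x, radii, grid)
    h = grid.spacing

    ex, ey, ez = _edge_dielectric(axes, ns, x, radii, eps_in, eps_out, grid)
    q_grid = _spread_charges(axes, ns, x, q)
    phi_b, bmask = _boundary_potential(axes, ns, x, q, eps_out if eps_out != eps_in else eps_in)

    # linear index bookkeeping over interior nodes
    nid = -np.ones(tuple(ns), dtype=int)
    interior = ~bmask
    nid[interior] = np.arange(int(interior.sum()))
    n_unknown = int(interior.sum())

    rows, cols, vals = [], [], []
    rhs = -4.0 * np.pi * q_grid[interior].ravel()

    I, J, K = np.nonzero(interior)
    diag = np.zeros(n_unknown)
    for (di, dj, dk, earr) in (
        (1, 0, 0, ex), (-1, 0, 0, ex),
        (0, 1, 0, ey), (0, -1, 0, ey),
        (0, 0, 1, ez), (0, 0, -1, ez),
    ):
        ni, nj, nk = I + di, J + dj, K + dk
        # edge array index: for the negative direction the edge is at index-1
        eidx = (I + min(di, 0), J + min(dj, 0), K + min(dk, 0))
        e = earr[eidx] * h
        me = nid[I, J, K]
        diag[me] += -e
        nb_interior = interior[ni, nj, nk]
        rows.extend(me[nb_interior])
        cols.extend(nid[ni[nb_interior], nj[nb_interior], nk[nb_interior]])
        vals.extend(e[nb_interior])
        # Dirichlet neighbours move to the right-hand side
        nb_b = ~nb_interior
        np.add.at(rhs, me[nb_b], -e[nb_b] * phi_b[ni[nb_b], nj[nb_b], nk[nb_b]])

    rows.extend(range(n_unknown))
    cols.extend(range(n_unknown))
    vals.extend(diag)
    A = coo_matrix((vals, (rows, cols)), shape=(n_unknown, n_unknown)).tocsr()

    # A is symmetric negative definite; negate for CG
    b = -rhs
    sol, info = cg(-A, b, rtol=grid.tolerance, atol=0.0, maxiter=grid.max_iterations)
    if info != 0:
        res = float(np.linalg.norm(-A @ sol - b) / max(np.linalg.norm(b), 1e-300))
        raise PBSolverError(
            f"PB solve did not converge after {grid.max_iterations} iterations "
            f"(relative residual {res:.2e})")

    phi = phi_b.copy()
    phi[interior] = sol
    return COULOMB_K * phi, axes


def _interp(phi: np.ndarray, axes, pos: np.ndarray) -> float:
    h = axes[0][1] - axes[0][0]
    f = [(pos[d] - axes[d][0]) / h for d in range(3)]
    i0 = [int(np.floor(f[d])) for d in range(3)]
    w = [f[d] - i0[d] for d in range(3)]
    val = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wt = ((w[0] if dx else 1 - w[0])
                      * (w[1] if dy else 1 - w[1])
                      * (w[2] if dz else 1 - w[2]))
                val += wt * phi[i0[0] + dx, i0[1] + dy, i0[2] + dz]
    return val


def pb_polar_energy(topology: Topology, coords: np.ndarray,
                    eps_in: float = 1.0, eps_out: float = 80.0,
                    grid: PBGrid = PBGrid(), indices=None) -> float:
    """Reaction-field energy ½ Σ q_i (φ_solvated − φ_reference)(r_i), kcal/mol.

    The reference solve uses ε_out = ε_in everywhere, so the grid self-energy
    cancels and only the solvent polarization response remains.
    """
    idx = np.arange(topology.n_atoms) if indices is None else np.asarray(sorted(indices), int)
    x = np.asarray(coords, float)[idx]
    q = topology.charges[idx]
    if not np.any(q):
        return 0.0
    phi_solv, axes = solve_pb(topology, coords, eps_in, eps_out, grid, indices)
    phi_ref, _ = solve_pb(topology, coords, eps_in, eps_in, grid, indices)
    energy = 0.0
    for pos, qi in zip(x, q):
        energy += 0.5 * qi * (_interp(phi_solv, axes, pos) - _interp(phi_ref, axes, pos))
    return float(energy)
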