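"""Conformational entropy by normal-mode analysis.

Protocol: each snapshot (complex, receptor and ligand separately, all taken
from the same frame under the single-trajectory convention) is energy
minimized in a distance-dependent dielectric of 4·r(i,j) until the gradient
RMS drops below 0.001 kcal/mol/Å (or a step cap is reached); the
mass-weighted Hessian M^{-1/2} H M^{-1/2} is diagonalized; rigid-body modes
are removed; and the remaining frequencies enter the standard
rigid-rotor / harmonic-oscillator entropy:

* translation — Sackur–Tetrode at 1 atm,
* rotation — classical rigid rotor from the principal moments of inertia
  (symmetry number 1: proteins are asymmetric),
* vibration — quantum harmonic oscillator per mode.

−TΔS = −T [S(complex) − S(receptor) − S(ligand)], averaged over snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .constants import (AMU_A2_TO_KG_M2, AMU_KG, ATM_PA, C_SI, H_SI, KB_SI,
                        KCAL_PER_MOL_A2_AMU_TO_S2, R_CAL,
                        DEFAULT_TEMPERATURE)
from .core import ComplexDefinition, Topology, Trajectory
from .forcefield import DielectricModel, hessian, total_potential

#: dielectric used during snapshot minimization ("4r(i,j)")
MINIMIZATION_DIELECTRIC = DielectricModel.distance_dependent(4.0)

GRADIENT_RMS_TOL = 0.001  # kcal/mol/Å
MAX_MINIMIZATION_STEPS = 10000

# modes with |frequency| below this are treated as rigid-body/numerical zero
ZERO_MODE_CMINV = 1.0


class MinimizationError(RuntimeError):
    pass


def _mass_weighted_rigid_basis(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted basis (≤6×3N) of rigid translations/rotations."""
    n = len(coords)
    com = np.sum(coords * masses[:, None], axis=0) / masses.sum()
    d = coords - com
    sq = np.sqrt(masses)
    vecs = []
    for axis in range(3):
        v = np.zeros((n, 3))
        v[:, axis] = sq
        vecs.append(v.reshape(-1))
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        vecs.append((np.cross(e, d) * sq[:, None]).reshape(-1))
    q, r = np.linalg.qr(np.array(vecs).T)
    keep = np.abs(np.diag(r)) > 1e-10 * np.abs(r).max()
    return q.T[keep]


@dataclass
class MinimizationResult:
    coords: np.ndarray
    energy: float
    gradient_rms: float
    n_steps: int
    converged: bool


@dataclass
class ModeSpectrum:
    """Vibrational frequencies (cm⁻¹, ascending) after rigid-body removal."""

    frequencies: np.ndarray
    n_zero_modes: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class EntropyResult:
    """Entropy components in cal/(mol·K) and −T·S_total in kcal/mol."""

    s_trans: float
    s_rot: float
    s_vib: float
    temperature: float

    @property
    def s_total(self) -> float:
        return self.s_trans + self.s_rot + self.s_vib

    @property
    def minus_TS(self) -> float:
        return -self.temperature * self.s_total / 1000.0


def gradient_rms(grad: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.asarray(grad) ** 2)))


def minimize_snapshot(topology: Topology, coords: np.ndarray,
                      model: DielectricModel = MINIMIZATION_DIELECTRIC,
                      max_steps: int = MAX_MINIMIZATION_STEPS,
                      grms_tol: float = GRADIENT_RMS_TOL) -> MinimizationResult:
    """Energy-minimize one snapshot to gradient RMS < ``grms_tol``.

    L-BFGS with the analytic gradient; stops early at an exact minimum and
    reports whether the gradient criterion (rather than the step cap) ended
    the run.  The energy is non-increasing across accepted steps.
    """
    x0 = np.asarray(coords, float)
    n3 = x0.size

    e0, g0 = total_potential(topology, x0, model)
    if gradient_rms(g0) < grms_tol:
        return MinimizationResult(x0.copy(), e0, gradient_rms(g0), 0, True)

    def fun(flat: np.ndarray):
        e, g = total_potential(topology, flat.reshape(-1, 3), model)
        return e, g.reshape(-1)

    res = _scipy_minimize(fun, x0.reshape(-1), jac=True, method="L-BFGS-B",
                          options={"maxiter": max_steps, "maxfun": 50 * max_steps,
                                   "gtol": 1e-12, "ftol": 1e-15})
    x = res.x.reshape(-1, 3)
    e, g = total_potential(topology, x, model)

    # Newton polishing: a few pseudo-inverse steps (rigid modes projected
    # out) push the residual gradient to ~1e-10, so normal-mode frequencies
    # do not depend on where the line-search happened to stop
    if topology.n_atoms <= 200:
        for _ in range(5):
            grms = gradient_rms(g)
            if grms < 1e-10:
                break
            H = hessian(topology, x, model)
            step_vec = -np.linalg.pinv(H, rcond=1e-8) @ g.reshape(-1)
            x_new = x + step_vec.reshape(-1, 3)
            e_new, g_new = total_potential(topology, x_new, model)
            if e_new > e + 1e-10 or gradient_rms(g_new) >= grms:
                break
            x, e, g = x_new, e_new, g_new

    if e > e0 + 1e-8:
        raise MinimizationError("minimization increased the energy")
    grms = gradient_rms(g)
    return MinimizationResult(x, e, grms, int(res.nit),
                              grms < grms_tol or bool(res.success) and grms < grms_tol)


def normal_modes(topology: Topology, coords: np.ndarray,
                 model: DielectricModel = MINIMIZATION_DIELECTRIC) -> ModeSpectrum:
    """Frequencies of the mass-weighted Hessian, rigid-body modes removed.

    Near-zero eigenvalues (|ν| below ``ZERO_MODE_CMINV``) are counted as
    rigid-body/zero modes and dropped: a diatomic yields five zeros and one
    vibration, a minimized nonlinear molecule exactly six zeros and 3N−6
    vibrations, and a dissociated dimer twelve (the six relative rigid-body
    motions are genuine zero modes at infinite separation).  Imaginary
    frequencies above the zero tolerance are recorded as warnings (the
    structure was not at a true minimum) and excluded.
    """
    H = hessian(topology, coords, model)
    m = np.repeat(topology.masses, 3)
    Hmw = H / np.sqrt(np.outer(m, m))
    # project the global rigid-body subspace out of the mass-weighted
    # Hessian: the six modes become exact zeros and the vibrational spectrum
    # is insensitive to the residual gradient and to rigid reorientation
    rb = _mass_weighted_rigid_basis(np.asarray(coords, float), topology.masses)
    P = np.eye(Hmw.shape[0]) - rb.T @ rb
    Hmw = P @ Hmw @ P
    evals = np.linalg.eigvalsh(Hmw)
    # λ [kcal/mol/Å²/amu] → ν̃ [cm⁻¹], sign kept for imaginary detection
    conv = np.sqrt(np.abs(evals) * KCAL_PER_MOL_A2_AMU_TO_S2) / (2.0 * np.pi * C_SI * 100.0)
    nu = np.sign(evals) * conv

    warnings = []
    zero = np.abs(nu) < ZERO_MODE_CMINV
    n_zero = int(zero.sum())
    order = np.argsort(np.abs(nu))
    keep = order[n_zero:]
    freqs = np.sort(nu[keep])
    imag = freqs[freqs < -ZERO_MODE_CMINV]
    if imag.size:
        warnings.append(f"{imag.size} imaginary frequencies (most negative "
                        f"{imag.min():.2f} cm⁻¹); structure not at a true minimum")
        freqs = freqs[freqs > 0]
    else:
        freqs = np.abs(freqs)
    return ModeSpectrum(np.sort(freqs), n_zero, warnings)


def principal_moments(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Principal moments of inertia (amu·Å²), ascending."""
    x = np.asarray(coords, float)
    m = np.asarray(masses, float)
    com = np.sum(x * m[:, None], axis=0) / m.sum()
    d = x - com
    I = np.zeros((3, 3))
    r2 = np.sum(d * d, axis=1)
    I[0, 0] = np.sum(m * (r2 - d[:, 0] ** 2))
    I[1, 1] = np.sum(m * (r2 - d[:, 1] ** 2))
    I[2, 2] = np.sum(m * (r2 - d[:, 2] ** 2))
    I[0, 1] = I[1, 0] = -np.sum(m * d[:, 0] * d[:, 1])
    I[0, 2] = I[2, 0] = -np.sum(m * d[:, 0] * d[:, 2])
    I[1, 2] = I[2, 1] = -np.sum(m * d[:, 1] * d[:, 2])
    return np.sort(np.linalg.eigvalsh(I))


def vibrational_entropy(frequencies: np.ndarray, T: float) -> float:
    """Quantum harmonic-oscillator entropy, cal/(mol·K)."""
    nu = np.asarray(frequencies, float)
    if np.any(nu <= 0):
        raise ValueError("vibrational frequencies must be positive")
    theta = H_SI * C_SI * 100.0 * nu / KB_SI  # K
    x = theta / T
    return float(R_CAL * np.sum(x / np.expm1(x) - np.log1p(-np.exp(-x))))


def translational_entropy(total_mass_amu: float, T: float,
                          pressure: float = ATM_PA) -> float:
    """Sackur–Tetrode translational entropy at ``pressure``, cal/(mol·K)."""
    m = total_mass_amu * AMU_KG
    q = (2.0 * np.pi * m * KB_SI * T / H_SI ** 2) ** 1.5 * KB_SI * T / pressure
    return R_CAL * (np.log(q) + 2.5)


def rotational_entropy(moments_amu_A2: np.ndarray, T: float,
                       sigma: float = 1.0) -> float:
    """Classical rigid-rotor entropy, cal/(mol·K); linear case handled."""
    I = np.sort(np.asarray(moments_amu_A2, float)) * AMU_A2_TO_KG_M2
    if I[0] < 1e-3 * I[2]:  # linear molecule: one vanishing moment
        q = 8.0 * np.pi ** 2 * I[2] * KB_SI * T / (sigma * H_SI ** 2)
        return R_CAL * (np.log(q) + 1.0)
    q = (np.sqrt(np.pi) / sigma) * (8.0 * np.pi ** 2 * KB_SI * T / H_SI ** 2) ** 1.5 \
        * np.sqrt(I[0] * I[1] * I[2])
    return R_CAL * (np.log(q) + 1.5)


def entropy_from_modes(spectrum: ModeSpectrum, total_mass_amu: float,
                       moments_amu_A2: np.ndarray,
                       T: float = DEFAULT_TEMPERATURE) -> EntropyResult:
    """Assemble S_trans + S_rot + S_vib from a mode spectrum."""
    if T <= 0:
        raise ValueError("temperature must be > 0")
    return EntropyResult(
        s_trans=translational_entropy(total_mass_amu, T),
        s_rot=rotational_entropy(moments_amu_A2, T),
        s_vib=vibrational_entropy(spectrum.frequencies, T) if len(spectrum.frequencies) else 0.0,
        temperature=T,
    )


def species_entropy(topology: Topology, coords: np.ndarray,
                    T: float = DEFAULT_TEMPERATURE,
                    model: DielectricModel = MINIMIZATION_DIELECTRIC,
                    max_steps: int = MAX_MINIMIZATION_STEPS) -> tuple[EntropyResult, MinimizationResult]:
    """Minimize one species and return its RRHO entropy."""
    mini = minimize_snapshot(topology, coords, model, max_steps=max_steps)
    spec = normal_modes(topology, mini.coords, model)
    ent = entropy_from_modes(spec, float(topology.masses.sum()),
                             principal_moments(mini.coords, topology.masses), T)
    return ent, mini


@dataclass
class BindingEntropyResult:
    minus_t_delta_s: float  # kcal/mol, ensemble mean
    se: float
    per_snapshot: np.ndarray
    single_snapshot: bool  # True when N=1 and the SE is 0 by convention


def binding_entropy(snapshots: np.ndarray | list[np.ndarray], topology: Topology,
                    cdef: ComplexDefinition, T: float = DEFAULT_TEMPERATURE,
                    max_steps: int = MAX_MINIMIZATION_STEPS) -> BindingEntropyResult:
    """Mean −TΔS ± SE over snapshots.

    Each snapshot's complex, receptor and ligand are minimized and analyzed
    independently from the same frame coordinates (single-trajectory
    convention); ΔS = S_complex − S_receptor − S_ligand.
    """
    rec_idx, lig_idx = cdef.receptor_index, cdef.ligand_index
    rec_top = topology.subset(rec_idx)
    lig_top = topology.subset(lig_idx)
    values = []
    for frame in snapshots:
        frame = np.asarray(frame, float)
        ent_c, _ = species_entropy(topology, frame, T, max_steps=max_steps)
        ent_r, _ = species_entropy(rec_top, frame[rec_idx], T, max_steps=max_steps)
        ent_l, _ = species_entropy(lig_top, frame[lig_idx], T, max_steps=max_steps)
        ds = ent_c.s_total - ent_r.s_total - ent_l.s_total  # cal/mol/K
        values.append(-T * ds / 1000.0)
    vals = np.asarray(values)
    n = len(vals)
    se = 0.0 if n == 1 else float(np.std(vals, ddof=1) / np.sqrt(n))
    return BindingEntropyResult(float(vals.mean()), se, vals, n == 1)


def nma_snapshot_frames(traj: Trajectory, interval_ps: float = 80.0) -> list[np.ndarray]:
    """Convenience extraction of frames at the entropy cadence."""
    from .pipeline import SnapshotPlan, extract_snapshots
    span = traj.times[-1] - traj.times[0]
    plan = SnapshotPlan(span_ps=span, interval_ps=interval_ps)
    return extract_snapshots(traj, plan)
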