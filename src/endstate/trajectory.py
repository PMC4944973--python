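"""Trajectory analytics: superposition, RMSF, PCA, rotation angle, OH-π.

RMSF and PCA operate on a selection (conventionally the Cα atoms) after
iteratively superposing every frame onto the converged mean structure, so
overall translation and rotation do not contaminate the fluctuations.  The
covariance matrix is C_ij = ⟨(x_i − ⟨x_i⟩)(x_j − ⟨x_j⟩)⟩ over the 3N
Cartesian coordinates of the selection.

The OH-π detector flags frames where a hydroxyl hydrogen sits 2.0–3.5 Å from
an aromatic six-ring centroid with the O→H vector elevated 65–90° above the
ring plane (90° = perpendicular approach).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import Trajectory


class UnderdeterminedError(ValueError):
    pass


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: Sequence[int] | None = None) -> tuple[np.ndarray, float]:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``reference``.

    The optimal transform is computed over ``selection`` (all atoms when
    None) and applied to all atoms; only proper rotations (det = +1) are
    allowed, so mirror images keep a positive RMSD.  Returns the transformed
    coordinates and the RMSD over the selection.
    """
    mob = np.asarray(mobile, float)
    ref = np.asarray(reference, float)
    sel = np.arange(len(mob)) if selection is None else np.asarray(list(selection), int)
    if len(sel) < 3:
        raise UnderdeterminedError("superposition needs at least 3 atoms")
    mc = mob[sel].mean(axis=0)
    rc = ref[sel].mean(axis=0)
    A = (mob[sel] - mc).T @ (ref[sel] - rc)
    U, _, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    out = (mob - mc) @ R.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((out[sel] - ref[sel]) ** 2, axis=1))))
    return out, rmsd


def _fit_to_mean(traj_coords: np.ndarray, selection: np.ndarray,
                 max_rounds: int = 10, tol: float = 1e-10) -> np.ndarray:
    """Iteratively superpose all frames to the running mean of the selection."""
    frames = np.array(traj_coords, float, copy=True)
    ref = frames[0]
    for _ in range(max_rounds):
        for f in range(len(frames)):
            frames[f], _ = superpose(frames[f], ref, selection)
        new_mean = frames.mean(axis=0)
        shift = float(np.max(np.abs(new_mean[selection] - ref[selection])))
        ref = new_mean
        if shift < tol:
            break
    for f in range(len(frames)):
        frames[f], _ = superpose(frames[f], ref, selection)
    return frames


def rmsd_series(traj: Trajectory, selection: Sequence[int],
                reference: np.ndarray | None = None) -> np.ndarray:
    """Per-frame RMSD (Å) to a reference (default: first frame)."""
    sel = np.asarray(list(selection), int)
    ref = traj.frames[0] if reference is None else np.asarray(reference, float)
    return np.array([superpose(fr, ref, sel)[1] for fr in traj.frames])


def rmsf(traj: Trajectory, selection: Sequence[int]) -> tuple[np.ndarray, bool]:
    """Per-atom RMSF (Å) over the selection after mean-structure fitting.

    Returns (rmsf values, flagged) where ``flagged`` is True for a
    single-frame trajectory (all zeros by convention).
    """
    sel = np.asarray(list(selection), int)
    if traj.n_frames == 1:
        return np.zeros(len(sel)), True
    frames = _fit_to_mean(traj.frames, sel)
    mean = frames.mean(axis=0)
    dev = frames[:, sel, :] - mean[sel]
    return np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0)), False


@dataclass
class PcaResult:
    """Eigendecomposition of the Cartesian covariance of a selection."""

    eigenvalues: np.ndarray  # Å², descending
    eigenvectors: np.ndarray  # (3N, n_modes), columns unit-norm
    projections: np.ndarray  # (n_frames, n_modes)
    mean_structure: np.ndarray  # (N_sel, 3)
    selection: np.ndarray


def pca(traj: Trajectory, selection: Sequence[int]) -> PcaResult:
    """PCA of the selection's Cartesian coordinates after superposition."""
    sel = np.asarray(list(selection), int)
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    frames = _fit_to_mean(traj.frames, sel)
    X = frames[:, sel, :].reshape(traj.n_frames, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    C = (Xc.T @ Xc) / traj.n_frames
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return PcaResult(evals, evecs, Xc @ evecs, mean.reshape(-1, 3), sel)


def porcupine_export(result: PcaResult, mode: int, scale: float,
                     path: str | Path) -> Path:
    """Write one PCA mode as per-atom arrows on the mean structure.

    Plain-text format, one header line then one record per selected atom:
    ``atom_index x y z dx dy dz`` (Å, displacement = eigenvector slice ×
    scale).  A PyMOL helper script drawing the arrows as CGO cylinders is
    written alongside with suffix ``.pml``.
    """
    if not (0 <= mode < len(result.eigenvalues)):
        raise IndexError(f"mode {mode} out of range")
    vec = result.eigenvectors[:, mode].reshape(-1, 3) * scale
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# porcupine vectors: atom_index x y z dx dy dz "
                 f"(mode {mode}, eigenvalue {result.eigenvalues[mode]:.6f} A^2, "
                 f"scale {scale:g})\n")
        for i, (xyz, d) in enumerate(zip(result.mean_structure, vec)):
            fh.write(f"{int(result.selection[i])} "
                     f"{xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f} "
                     f"{d[0]:.6f} {d[1]:.6f} {d[2]:.6f}\n")
    pml = path.with_suffix(".pml")
    with pml.open("w") as fh:
        fh.write("from pymol.cgo import CYLINDER\nobj=[]\n")
        for xyz, d in zip(result.mean_structure, vec):
            tip = xyz + d
            fh.write(f"obj+=[CYLINDER,{xyz[0]:.3f},{xyz[1]:.3f},{xyz[2]:.3f},"
                     f"{tip[0]:.3f},{tip[1]:.3f},{tip[2]:.3f},0.1,1,0,0,1,0,0]\n")
        fh.write("cmd.load_cgo(obj,'porcupine')\n")
    return path


def read_porcupine(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read back a porcupine file → (atom indices, positions, vectors)."""
    idx, pos, vec = [], [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        parts = line.split()
        idx.append(int(parts[0]))
        pos.append([float(v) for v in parts[1:4]])
        vec.append([float(v) for v in parts[4:7]])
    return np.array(idx), np.array(pos), np.array(vec)


def rotation_angle(traj: Trajectory, atom_a: int, vertex: int, atom_b: int
                   ) -> tuple[np.ndarray, float, float]:
    """Planar angle (degrees) at ``vertex`` per frame, plus mean ± sample SD.

    This is the rigid-rotation metric: three marker atoms (conventionally
    three Cα atoms, the physically central one at the vertex) tracked over
    the trajectory.
    """
    if len({atom_a, vertex, atom_b}) != 3:
        raise ValueError("the three atoms must be distinct")
    u = traj.frames[:, atom_a, :] - traj.frames[:, vertex, :]
    v = traj.frames[:, atom_b, :] - traj.frames[:, vertex, :]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("coincident points: angle undefined")
    ct = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
    angles = np.degrees(np.arccos(ct))
    sd = float(np.std(angles, ddof=1)) if len(angles) > 1 else 0.0
    return angles, float(angles.mean()), sd


@dataclass(frozen=True)
class OhPiCriterion:
    """Strong-interaction windows: elevation angle (deg) and H–centroid (Å)."""

    angle_min: float = 65.0
    angle_max: float = 90.0
    dist_min: float = 2.0
    dist_max: float = 3.5

    def __post_init__(self) -> None:
        if not (self.angle_min < self.angle_max and self.dist_min < self.dist_max):
            raise ValueError("criterion windows must be nonempty")


@dataclass
class OhPiResult:
    flags: np.ndarray  # bool per frame
    distances: np.ndarray  # Å
    angles: np.ndarray  # degrees
    occupancy: float
    planarity_warning: bool = False


def ring_plane(ring_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """(centroid, unit normal, RMS out-of-plane) of a ring by least squares."""
    centroid = ring_coords.mean(axis=0)
    d = ring_coords - centroid
    _, s, Vt = np.linalg.svd(d, full_matrices=False)
    normal = Vt[2]
    rms_dev = float(np.sqrt(np.mean((d @ normal) ** 2)))
    return centroid, normal, rms_dev


def oh_pi_occupancy(traj: Trajectory, donor_o: int, donor_h: int,
                    ring_atoms: Sequence[int],
                    criterion: OhPiCriterion = OhPiCriterion()) -> OhPiResult:
    """Per-frame OH-π geometry and the fraction of "strong" frames.

    distance = |H − ring centroid|; angle = elevation of the O→H vector
    above the ring's least-squares plane.  A frame is strong iff both fall
    inside the criterion windows.
    """
    ring = np.asarray(list(ring_atoms), int)
    if len(ring) != 6:
        raise ValueError("ring must have exactly 6 atoms")
    n = traj.n_frames
    dist = np.empty(n)
    ang = np.empty(n)
    planarity_warning = False
    for f in range(n):
        rc = traj.frames[f, ring, :]
        centroid, normal, rms_dev = ring_plane(rc)
        if rms_dev > 0.3:
            planarity_warning = True
        h = traj.frames[f, donor_h, :]
        o = traj.frames[f, donor_o, :]
        dist[f] = float(np.linalg.norm(h - centroid))
        oh = h - o
        oh_norm = np.linalg.norm(oh)
        if oh_norm == 0:
            raise ValueError("O and H coincide")
        ang[f] = float(np.degrees(np.arcsin(min(1.0, abs(np.dot(oh, normal)) / oh_norm))))
    flags = ((ang >= criterion.angle_min) & (ang <= criterion.angle_max)
             & (dist >= criterion.dist_min) & (dist <= criterion.dist_max))
    return OhPiResult(flags, dist, ang, float(flags.mean()), planarity_warning)
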