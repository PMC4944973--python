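"""Synthetic toy complexes, trajectories and mutants.

The generator builds a two-chain "protein" dimer from residue archetypes —
charged (+/−), polar hydroxyl donor, aromatic six-ring, apolar and
glycine-like — arranged on two parallel backbones whose side chains face
each other across an interface.  Contact pairs are aligned geometrically,
so a serine-like O–H can be placed directly over a phenylalanine-like ring
face (the OH-π construction) and a lysine/aspartate pair forms a salt
bridge.  Bonded equilibrium values (bond lengths, angles, torsion phases)
are set to the built geometry, so the mean structure is an approximate
minimum of the force field — the near-harmonic regime that the RMSF / PCA /
NMA analyses assume.

Trajectories are frames of mean + independent Gaussian noise + optional
planted collective modes (no autocorrelation); mutants are side-chain
rewrites (truncation to alanine, hydroxyl→carboxylate charge swap,
phosphorylation) that touch only the targeted residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Atom, BondTerm, AngleTerm, ComplexDefinition, DihedralTerm, \
    Residue, Topology, Trajectory, validate_complex
from .params import ELEMENT_PARAMS, lcpo_coefficients

BACKBONE_NAMES = ("N", "CA", "C")
CA_SPACING = 3.8  # Å between consecutive Cα along a chain

# side-chain templates: name → [(atom name, element, charge, local xyz)],
# in a frame with CA at the origin and the side chain along +y.  Joints are
# bent (~157°) so no three bonded atoms are colinear (angle gradients are
# singular at θ = 180°); the serine O–H bond stays parallel to y so the
# hydroxyl approaches a facing ring face perpendicularly.
_SIDE_CHAINS: dict[str, list[tuple[str, str, float, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", "C", 0.0, (0.0, 1.53, 0.0))],
    "LYS": [("CB", "C", 0.0, (0.0, 1.53, 0.0)),
            ("NZ", "N", 1.0, (0.55, 2.89, 0.0))],
    "ASP": [("CB", "C", 0.0, (0.0, 1.53, 0.0)),
            ("OD", "O", -1.0, (0.55, 2.68, 0.0))],
    "SER": [("CB", "C", 0.20, (0.0, 1.53, 0.0)),
            ("OG", "O", -0.65, (0.55, 2.83, 0.0)),
            ("HG", "H", 0.45, (0.55, 3.79, 0.0))],
    "SEP": [("CB", "C", 0.20, (0.0, 1.53, 0.0)),  # phospho-serine, net −2
            ("OG", "O", -0.50, (0.55, 2.83, 0.0)),
            ("P", "P", 1.30, (0.0, 4.27, 0.0)),
            ("OP1", "O", -1.00, (1.40, 4.75, 0.0)),
            ("OP2", "O", -1.00, (-0.70, 4.75, 1.212)),
            ("OP3", "O", -1.00, (-0.70, 4.75, -1.212))],
    "PHE": [("CB", "C", 0.0, (0.0, 1.53, 0.0)),
            ("CG", "C", 0.0, (0.55, 2.96, 0.0)),
            ("CD1", "C", 0.0, (1.25, 2.96, 1.212)),
            ("CE1", "C", 0.0, (2.65, 2.96, 1.212)),
            ("CZ", "C", 0.0, (3.35, 2.96, 0.0)),
            ("CE2", "C", 0.0, (2.65, 2.96, -1.212)),
            ("CD2", "C", 0.0, (1.25, 2.96, -1.212))],
}

# intra-residue side-chain bonds by atom name (CA implicit for CB/GLY)
_SIDE_BONDS: dict[str, list[tuple[str, str]]] = {
    "GLY": [],
    "ALA": [("CA", "CB")],
    "LYS": [("CA", "CB"), ("CB", "NZ")],
    "ASP": [("CA", "CB"), ("CB", "OD")],
    "SER": [("CA", "CB"), ("CB", "OG"), ("OG", "HG")],
    "SEP": [("CA", "CB"), ("CB", "OG"), ("OG", "P"),
            ("P", "OP1"), ("P", "OP2"), ("P", "OP3")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"),
            ("CE1", "CZ"), ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG")],
}

# interface "anchor" of each archetype (local frame): the side-chain tip used
# to align contact pairs; PHE anchors at its ring centroid
_ANCHORS: dict[str, tuple[float, float, float]] = {
    "GLY": (0.0, 0.0, 0.0),
    "ALA": (0.0, 1.53, 0.0),
    "LYS": (0.55, 2.89, 0.0),
    "ASP": (0.55, 2.68, 0.0),
    "SER": (0.55, 3.79, 0.0),
    "SEP": (0.0, 4.27, 0.0),
    "PHE": (1.95, 2.96, 0.0),  # ring centroid
}

ARCHETYPES = tuple(sorted(_SIDE_CHAINS))

_BOND_K_HEAVY = 300.0  # kcal/mol/Å²
_BOND_K_H = 400.0
_ANGLE_K = 63.0  # kcal/mol/rad²
_ANGLE_K_H = 50.0
_DIHEDRAL_V_HALF = 2.0  # kcal/mol


class ConstructionError(ValueError):
    """The requested toy geometry cannot be realized."""


@dataclass(frozen=True)
class ToyComplexSpec:
    """Two archetype sequences, interface contact pairs, and a seed.

    ``contact_pairs`` are (index in chain_a, index in chain_b) residue pairs
    whose side-chain anchors are aligned across the interface with gap
    ``gap`` (Å, applied to the first pair).
    """

    chain_a: tuple[str, ...]
    chain_b: tuple[str, ...]
    contact_pairs: tuple[tuple[int, int], ...] = ()
    gap: float = 2.5
    seed: int = 0
    jitter: float = 0.02  # Å isotropic positional jitter per atom

    def __post_init__(self) -> None:
        if not self.chain_a or not self.chain_b:
            raise ConstructionError("each chain needs at least one residue")
        for seq in (self.chain_a, self.chain_b):
            for name in seq:
                if name not in _SIDE_CHAINS:
                    raise ConstructionError(f"unknown archetype {name!r}")
        for i, j in self.contact_pairs:
            if not (0 <= i < len(self.chain_a) and 0 <= j < len(self.chain_b)):
                raise ConstructionError(f"contact pair ({i},{j}) out of range")


def _make_atom(serial: int, name: str, element: str, charge: float,
               residue_index: int, chain_id: str) -> Atom:
    rh, eps, rad, mass = ELEMENT_PARAMS[element]
    return Atom(serial=serial, name=name, element=element,
                residue_index=residue_index, chain_id=chain_id, charge=charge,
                lj_rmin_half=rh, lj_epsilon=eps, intrinsic_radius=rad,
                mass=mass, lcpo_params=(0.0, 0.0, 0.0, 0.0))


def _residue_records(arch: str, ca: np.ndarray, flip: bool):
    """(name, element, charge, position) records for one residue."""
    sign = -1.0 if flip else 1.0
    recs = [("N", "N", 0.0, ca + np.array([-1.25, 0.0, 0.773])),
            ("CA", "C", 0.0, ca.copy()),
            ("C", "C", 0.0, ca + np.array([1.25, 0.0, 0.773]))]
    for name, el, q, off in _SIDE_CHAINS[arch]:
        off = np.asarray(off, float)
        recs.append((name, el, q, ca + np.array([off[0], sign * off[1], off[2]])))
    return recs


def assemble(atom_records: list[tuple[str, str, float, str, int, str]],
             bond_pairs: list[tuple[int, int]], coords: np.ndarray,
             residue_spans: list[tuple[str, str, int, int]]) -> Topology:
    """Build a Topology whose bonded equilibria match ``coords`` exactly.

    ``atom_records`` rows are (name, element, charge, chain_id,
    residue_index, _); angles are enumerated from the bond graph (one term
    per neighbour pair), dihedrals one per central bond, with θ0 and the
    torsion phase taken from the supplied geometry so the structure sits at
    a bonded-energy minimum.  LCPO coefficients are assigned from the
    bonded-heavy-neighbour counts.
    """
    n = len(atom_records)
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in bond_pairs:
        adj[i].add(j)
        adj[j].add(i)

    atoms = []
    for serial, (name, el, q, chain, ridx, _) in enumerate(atom_records):
        a = _make_atom(serial + 1, name, el, q, ridx, chain)
        if el != "H":
            heavy_nb = sum(1 for j in adj[serial] if atom_records[j][1] != "H")
            a = Atom(**{**a.__dict__, "lcpo_params": lcpo_coefficients(el, heavy_nb)})
        atoms.append(a)

    residues = [Residue(name, label, start, stop)
                for name, label, start, stop in residue_spans]

    bonds = []
    for i, j in bond_pairs:
        b0 = float(np.linalg.norm(coords[i] - coords[j]))
        k = _BOND_K_H if "H" in (atoms[i].element, atoms[j].element) else _BOND_K_HEAVY
        bonds.append(BondTerm(i, j, k, b0))

    angles = []
    for j in range(n):
        nbs = sorted(adj[j])
        for a_pos in range(len(nbs)):
            for b_pos in range(a_pos + 1, len(nbs)):
                i, k = nbs[a_pos], nbs[b_pos]
                u = coords[i] - coords[j]
                v = coords[k] - coords[j]
                ct = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
                theta0 = float(np.arccos(np.clip(ct, -1.0, 1.0)))
                kk = _ANGLE_K_H if "H" in (atoms[i].element, atoms[k].element) else _ANGLE_K
                angles.append(AngleTerm(i, j, k, kk, theta0))

    dihedrals = []
    for j, k in bond_pairs:
        others_j = sorted(adj[j] - {k})
        others_k = sorted(adj[k] - {j})
        if not others_j or not others_k:
            continue
        i, l = others_j[0], others_k[0]
        b1, b2, b3 = coords[j] - coords[i], coords[k] - coords[j], coords[l] - coords[k]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        if np.dot(n1, n1) < 1e-12 or np.dot(n2, n2) < 1e-12:
            continue
        phi = float(np.arctan2(np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2),
                               np.dot(n1, n2)))
        dihedrals.append(DihedralTerm(i, j, k, l, _DIHEDRAL_V_HALF, 1,
                                      float((phi + np.pi) % (2.0 * np.pi))))

    return Topology(atoms, residues, bonds, angles, dihedrals)


def make_toy_complex(spec: ToyComplexSpec
                     ) -> tuple[Topology, np.ndarray, ComplexDefinition]:
    """Build a toy two-chain complex: Topology, mean coords, partition.

    Chain A ("A", receptor) lies along x at y = 0 with side chains pointing
    +y; chain B ("B", ligand) is offset to y = D with side chains pointing
    −y.  D and chain B's x-offset are set so the first contact pair's
    anchors align with separation ``spec.gap``; further contact pairs must
    be geometrically consistent or a :class:`ConstructionError` is raised.
    """
    anchors_a = {}
    for i, arch in enumerate(spec.chain_a):
        off = np.asarray(_ANCHORS[arch], float)
        anchors_a[i] = np.array([i * CA_SPACING + off[0], off[1], off[2]])

    # chain B placement: global x-shift and interface distance from the
    # first contact pair, then a small per-residue x-tweak for every further
    # contacted residue so its anchor also aligns
    res_shift: dict[int, float] = {}
    if spec.contact_pairs:
        if len({j for _, j in spec.contact_pairs}) != len(spec.contact_pairs):
            raise ConstructionError("a chain-B residue may appear in one contact pair only")
        i0, j0 = spec.contact_pairs[0]
        off_b = np.asarray(_ANCHORS[spec.chain_b[j0]], float)
        x_shift = anchors_a[i0][0] - (j0 * CA_SPACING + off_b[0])
        D = anchors_a[i0][1] + spec.gap + off_b[1]
        for i, j in spec.contact_pairs[1:]:
            offb = np.asarray(_ANCHORS[spec.chain_b[j]], float)
            delta = anchors_a[i][0] - (j * CA_SPACING + offb[0] + x_shift)
            if abs(delta) > 2.5:
                raise ConstructionError(
                    f"contact pair ({i},{j}) incompatible with pair ({i0},{j0}): "
                    f"anchor x mismatch {abs(delta):.2f} Å")
            if abs(delta) > 1e-12:
                res_shift[j] = delta
    else:
        x_shift = 0.0
        D = 9.0

    rng = np.random.default_rng(spec.seed)

    atom_records: list[tuple[str, str, float, str, int, str]] = []
    coords: list[np.ndarray] = []
    spans: list[tuple[str, str, int, int]] = []
    bond_pairs: list[tuple[int, int]] = []
    receptor: list[int] = []
    ligand: list[int] = []

    def add_chain(seq, chain_id, flip, x_shift_chain, y_base, sink, shifts):
        prev_c = None
        for ridx, arch in enumerate(seq):
            ca = np.array([ridx * CA_SPACING + x_shift_chain
                           + shifts.get(ridx, 0.0), y_base, 0.0])
            recs = _residue_records(arch, ca, flip)
            start = len(atom_records)
            name_to_idx = {}
            jit = rng.normal(0.0, spec.jitter, size=(len(recs), 3)) \
                if spec.jitter > 0 else np.zeros((len(recs), 3))
            for k, (name, el, q, pos) in enumerate(recs):
                idx = len(atom_records)
                atom_records.append((name, el, q, chain_id, len(spans), ""))
                coords.append(pos + jit[k])
                name_to_idx[name] = idx
                sink.append(idx)
            spans.append((arch, f"{chain_id}:{arch}{ridx + 1}", start, len(atom_records)))
            bond_pairs.append((name_to_idx["N"], name_to_idx["CA"]))
            bond_pairs.append((name_to_idx["CA"], name_to_idx["C"]))
            if prev_c is not None:
                bond_pairs.append((prev_c, name_to_idx["N"]))
            prev_c = name_to_idx["C"]
            for a, b in _SIDE_BONDS[arch]:
                bond_pairs.append((name_to_idx[a], name_to_idx[b]))

    add_chain(spec.chain_a, "A", False, 0.0, 0.0, receptor, {})
    add_chain(spec.chain_b, "B", True, x_shift, D, ligand, res_shift)

    xyz = np.array(coords)
    topology = assemble(atom_records, bond_pairs, xyz, spans)
    cdef = validate_complex(topology, ComplexDefinition(frozenset(receptor),
                                                        frozenset(ligand)))
    return topology, xyz, cdef


def net_charge(topology: Topology) -> float:
    return float(topology.charges.sum())


@dataclass(frozen=True)
class FluctuationSpec:
    """Near-harmonic fluctuation model for synthetic trajectories.

    ``isotropic_sigma`` is the per-axis standard deviation (Å) of the
    frame-independent Gaussian noise; ``modes`` plant collective motions as
    (3N direction, variance Å²) pairs (directions are orthonormalized).
    """

    n_frames: int
    dt_ps: float = 10.0
    isotropic_sigma: float = 0.1
    modes: tuple[tuple[tuple[float, ...], float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.dt_ps <= 0:
            raise ValueError("need n_frames >= 1 and dt_ps > 0")
        if self.isotropic_sigma < 0 or any(v < 0 for _, v in self.modes):
            raise ValueError("variances must be >= 0")


def make_trajectory(topology: Topology, mean_coords: np.ndarray,
                    fluct: FluctuationSpec) -> Trajectory:
    """Sample frames = mean + isotropic noise + planted collective modes."""
    rng = np.random.default_rng(fluct.seed)
    n_atoms = topology.n_atoms
    mean = np.asarray(mean_coords, float)
    if mean.shape != (n_atoms, 3):
        raise ValueError("mean coords shape mismatch")

    dirs = np.array([d for d, _ in fluct.modes], float).reshape(-1, 3 * n_atoms)
    variances = np.array([v for _, v in fluct.modes], float)
    if len(dirs):
        q, _ = np.linalg.qr(dirs.T)
        dirs = q.T[: len(variances)]

    frames = np.empty((fluct.n_frames, n_atoms, 3))
    for f in range(fluct.n_frames):
        x = mean.copy()
        if fluct.isotropic_sigma > 0:
            x = x + rng.normal(0.0, fluct.isotropic_sigma, size=(n_atoms, 3))
        for m in range(len(variances)):
            x = x + (rng.normal(0.0, np.sqrt(variances[m]))
                     * dirs[m].reshape(n_atoms, 3))
        frames[f] = x
    times = fluct.dt_ps * np.arange(1, fluct.n_frames + 1)
    return Trajectory(topology, frames, times)


def rigid_body_subspace(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6×3N) of rigid translations/rotations at ``coords``."""
    x = np.asarray(coords, float)
    n = len(x)
    com = x.mean(axis=0)
    d = x - com
    basis = []
    for axis in range(3):
        v = np.zeros((n, 3))
        v[:, axis] = 1.0
        basis.append(v.reshape(-1))
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        basis.append(np.cross(e, d).reshape(-1))
    q, _ = np.linalg.qr(np.array(basis).T)
    return q.T


def internal_mode_direction(coords: np.ndarray, seed: int = 0) -> np.ndarray:
    """A random unit 3N direction orthogonal to all rigid-body motions.

    Useful for planting collective modes that survive superposition to the
    mean structure (pure translations/rotations are removed by fitting).
    """
    x = np.asarray(coords, float)
    rng = np.random.default_rng(seed)
    v = rng.normal(size=x.size)
    rb = rigid_body_subspace(x)
    v -= rb.T @ (rb @ v)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

MUTATION_KINDS = ("truncate", "charge_swap", "phospho")

_BACKBONE_SET = {"N", "CA", "C"}


class MutationError(ValueError):
    pass


def _rebuild(topology: Topology, coords: np.ndarray, target_label: str,
             new_residue: list[tuple[str, str, float, np.ndarray]] | None,
             new_name: str | None,
             frames: Sequence[np.ndarray] | None = None):
    """Rebuild the topology with the target residue's records replaced.

    ``new_residue`` supplies (name, element, charge, position) for the
    replacement residue; positions for extra frames are produced by the
    caller via ``frames`` replacement lists.
    """
    target = topology.residue_by_label(target_label)
    atom_records = []
    new_coords = []
    spans = []
    old_to_new: dict[int, int] = {}
    for r in topology.residues:
        start = len(atom_records)
        if r.label == target_label and new_residue is not None:
            for name, el, q, pos in new_residue:
                atom_records.append((name, el, q,
                                     topology.atoms[r.start].chain_id, len(spans), ""))
                new_coords.append(np.asarray(pos, float))
            spans.append((new_name or r.name, r.label, start, len(atom_records)))
            # map surviving backbone atoms for bond remap
            for i in r.atom_indices:
                nm = topology.atoms[i].name
                for k, (name, *_rest) in enumerate(new_residue):
                    if name == nm:
                        old_to_new[i] = start + k
                        break
        else:
            for i in r.atom_indices:
                a = topology.atoms[i]
                old_to_new[i] = len(atom_records)
                atom_records.append((a.name, a.element, a.charge, a.chain_id,
                                     len(spans), ""))
                new_coords.append(coords[i])
            spans.append((r.name, r.label, start, len(atom_records)))

    # bonds: keep every bond whose atoms survive; regenerate target's
    # side-chain bonds from the archetype bond list
    bond_pairs = set()
    for b in topology.bonds:
        if b.i in old_to_new and b.j in old_to_new:
            i, j = old_to_new[b.i], old_to_new[b.j]
            ri = atom_records[i][4]
            rj = atom_records[j][4]
            tgt = [k for k, s in enumerate(spans) if s[1] == target_label][0]
            if ri == tgt == rj:
                continue  # intra-target bonds regenerated below
            bond_pairs.add((min(i, j), max(i, j)))
    tgt_span = [s for s in spans if s[1] == target_label][0]
    tgt_names = {atom_records[i][0]: i for i in range(tgt_span[2], tgt_span[3])}
    arch = tgt_span[0]
    intra = [("N", "CA"), ("CA", "C"), ("CB", "HB1")] + _SIDE_BONDS.get(arch, [])
    for a, b in intra:
        if a in tgt_names and b in tgt_names:
            i, j = tgt_names[a], tgt_names[b]
            bond_pairs.add((min(i, j), max(i, j)))

    xyz = np.array(new_coords)
    new_top = assemble(atom_records, sorted(bond_pairs), xyz, spans)
    return new_top, xyz, old_to_new, target


def _side_frame(coords: np.ndarray, cb: int, tip: int):
    u = coords[tip] - coords[cb]
    u = u / np.linalg.norm(u)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    w1 = np.cross(u, ref)
    w1 /= np.linalg.norm(w1)
    w2 = np.cross(u, w1)
    return u, w1, w2


def make_mutant(topology: Topology, coords: np.ndarray, residue_label: str,
                kind: str) -> tuple[Topology, np.ndarray]:
    """Apply a point mutation; only the targeted residue's atoms change.

    Kinds: ``truncate`` (side chain → alanine: first side-chain atom past Cβ
    becomes a hydrogen at 1.09 Å along its old direction, the rest are
    deleted, Cβ reset to the alanine archetype — a residue already alanine
    or glycine is returned unchanged); ``charge_swap`` (serine-like −OH →
    carboxylate-like −O⁻, net charge 0 → −1); ``phospho`` (serine-like −OH
    → phosphate, net −2).  Double mutants compose two calls; composition is
    order-independent for distinct residues.
    """
    if kind not in MUTATION_KINDS:
        raise MutationError(f"unknown mutation kind {kind!r}")
    coords = np.asarray(coords, float)
    res = topology.residue_by_label(residue_label)
    names = {topology.atoms[i].name: i for i in res.atom_indices}

    backbone = [(n, topology.atoms[names[n]].element, topology.atoms[names[n]].charge,
                 coords[names[n]]) for n in BACKBONE_NAMES]

    if kind == "truncate":
        side = [i for i in res.atom_indices
                if topology.atoms[i].name not in _BACKBONE_SET | {"CB"}]
        if "CB" not in names or not side:
            return topology, coords.copy()  # alanine/glycine: identity
        cb = names["CB"]
        gamma = [i for i in side if any(
            (b.i == cb and b.j == i) or (b.j == cb and b.i == i)
            for b in topology.bonds)]
        u = coords[gamma[0]] - coords[cb]
        u /= np.linalg.norm(u)
        new_res = backbone + [("CB", "C", 0.0, coords[cb]),
                              ("HB1", "H", 0.0, coords[cb] + 1.09 * u)]
        new_top, xyz, _, _ = _rebuild(topology, coords, residue_label, new_res, "ALA")
        return new_top, xyz

    if kind == "charge_swap":
        if res.name != "SER":
            raise MutationError(f"charge_swap applies to SER archetypes, not {res.name}")
        new_res = backbone + [("CB", "C", 0.0, coords[names["CB"]]),
                              ("OD", "O", -1.0, coords[names["OG"]])]
        new_top, xyz, _, _ = _rebuild(topology, coords, residue_label, new_res, "ASP")
        return new_top, xyz

    # phospho
    if res.name != "SER":
        raise MutationError(f"phospho applies to SER archetypes, not {res.name}")
    cb, og = names["CB"], names["OG"]
    u, w1, w2 = _side_frame(coords, cb, og)
    # branch ~23° off the O–C axis so the new P joint is not colinear
    p = coords[og] + 1.60 * (0.921 * u + 0.390 * w1)
    op = [p + 1.48 * (0.324 * u + 0.946 * w1),
          p + 1.48 * (0.324 * u - 0.473 * w1 + 0.819 * w2),
          p + 1.48 * (0.324 * u - 0.473 * w1 - 0.819 * w2)]
    new_res = backbone + [("CB", "C", 0.20, coords[cb]),
                          ("OG", "O", -0.50, coords[og]),
                          ("P", "P", 1.30, p),
                          ("OP1", "O", -1.00, op[0]),
                          ("OP2", "O", -1.00, op[1]),
                          ("OP3", "O", -1.00, op[2])]
    new_top, xyz, _, _ = _rebuild(topology, coords, residue_label, new_res, "SEP")
    return new_top, xyz
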