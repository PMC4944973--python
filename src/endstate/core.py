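"""Domain types shared by every stage of the end-state pipeline.

A :class:`Topology` carries the static description of one molecular system
(atoms with physical parameters, residue spans, bonded terms); a
:class:`Trajectory` is an ordered stack of coordinate frames for a fixed
topology; a :class:`ComplexDefinition` partitions the atoms into receptor
and ligand under the single-trajectory convention (receptor, ligand and
complex energies are all evaluated on the same frames, so internal bonded
energies cancel in differences).

Energetic results are collected in :class:`EnergyComponents` (one snapshot),
:class:`BindingEnergyReport` (ensemble means ± standard errors and the
assembled binding free energy ΔG_bind = ⟨ΔE_ele⟩+⟨ΔE_vdw⟩+⟨ΔG_polar⟩+
⟨ΔG_SA⟩+(−TΔS)), :class:`ResidueEnergyTable` (per-residue decomposition of
the effective binding energy) and :class:`AlaScanResult` (computational
alanine scanning).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when a domain-type invariant is violated."""


@dataclass(frozen=True)
class Atom:
    """One atom with the per-atom physical parameters the pipeline needs.

    charge is in elementary charges; lj_rmin_half (Å) and lj_epsilon
    (kcal/mol) are the Lennard-Jones Rmin/2 and well depth; intrinsic_radius
    (Å) is the GB/PB/SASA radius; lcpo_params are the four dimensionless
    LCPO coefficients (P1..P4) — None means unparameterized (an error for
    heavy atoms in SASA calls), while an all-zero tuple is a valid
    "buried by convention" assignment (e.g. quaternary carbon).
    """

    serial: int
    name: str
    element: str
    residue_index: int
    chain_id: str
    charge: float = 0.0
    lj_rmin_half: float = 1.7
    lj_epsilon: float = 0.1
    intrinsic_radius: float = 1.5
    mass: float = 12.011
    lcpo_params: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValidationError(f"atom {self.serial}: mass must be > 0")
        if self.intrinsic_radius <= 0:
            raise ValidationError(f"atom {self.serial}: intrinsic_radius must be > 0")
        if self.lj_epsilon < 0:
            raise ValidationError(f"atom {self.serial}: lj_epsilon must be >= 0")


@dataclass(frozen=True)
class Residue:
    """A contiguous span of atoms [start, stop) with a name and label.

    Labels carry chain identity (e.g. ``"A:SER6"``) because residue numbering
    may overlap between the two chains of a complex.
    """

    name: str
    label: str
    start: int
    stop: int

    @property
    def atom_indices(self) -> range:
        return range(self.start, self.stop)


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    k: float  # kcal/mol/Å², E = k (r − b0)²  (no ½; Amber convention)
    b0: float  # Å


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int
    k: int
    force_k: float  # kcal/mol/rad², E = k (θ − θ0)²
    theta0: float  # rad


@dataclass(frozen=True)
class DihedralTerm:
    i: int
    j: int
    k: int
    l: int
    v_half: float  # kcal/mol, E = v_half (1 + cos(n φ − γ))
    n: int
    gamma: float  # rad


@dataclass
class Topology:
    """Atoms, residue spans and bonded terms for one molecular system."""

    atoms: list[Atom]
    residues: list[Residue]
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    dihedrals: list[DihedralTerm] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        covered = []
        for r in self.residues:
            if not (0 <= r.start < r.stop <= n):
                raise ValidationError(f"residue {r.label}: span [{r.start},{r.stop}) out of range")
            covered.extend(range(r.start, r.stop))
        if covered != list(range(n)):
            raise ValidationError("residue spans must partition the atom list in order")
        for b in self.bonds:
            if b.i == b.j:
                raise ValidationError(f"bond ({b.i},{b.j}) is irreflexive")
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValidationError(f"bond ({b.i},{b.j}) index out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.intrinsic_radius for a in self.atoms])

    @property
    def lj_rmin_half(self) -> np.ndarray:
        return np.array([a.lj_rmin_half for a in self.atoms])

    @property
    def lj_epsilon(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms])

    def residue_of_atom(self, i: int) -> Residue:
        for r in self.residues:
            if r.start <= i < r.stop:
                return r
        raise IndexError(i)

    def residue_by_label(self, label: str) -> Residue:
        for r in self.residues:
            if r.label == label:
                return r
        raise KeyError(label)

    def bonded_neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append(b.j)
            elif b.j == i:
                out.append(b.i)
        return sorted(out)

    def subset(self, indices: Sequence[int]) -> "Topology":
        """Extract the sub-topology over ``indices`` (ascending, remapped to 0..m).

        Bonded terms are kept only when every participating atom survives;
        residue spans are rebuilt from the surviving atoms.
        """
        idx = sorted(indices)
        remap = {old: new for new, old in enumerate(idx)}
        atoms = [replace(self.atoms[i], residue_index=-1) for i in idx]
        # rebuild residues from the original spans
        residues: list[Residue] = []
        new_atoms: list[Atom] = []
        cursor = 0
        for ridx, r in enumerate(self.residues):
            keep = [i for i in r.atom_indices if i in remap]
            if not keep:
                continue
            for i in keep:
                new_atoms.append(replace(self.atoms[i], residue_index=len(residues)))
            residues.append(Residue(r.name, r.label, cursor, cursor + len(keep)))
            cursor += len(keep)
        assert len(new_atoms) == len(atoms)
        bonds = [replace(b, i=remap[b.i], j=remap[b.j]) for b in self.bonds
                 if b.i in remap and b.j in remap]
        angles = [replace(a, i=remap[a.i], j=remap[a.j], k=remap[a.k]) for a in self.angles
                  if a.i in remap and a.j in remap and a.k in remap]
        dihedrals = [replace(d, i=remap[d.i], j=remap[d.j], k=remap[d.k], l=remap[d.l])
                     for d in self.dihedrals
                     if d.i in remap and d.j in remap and d.k in remap and d.l in remap]
        return Topology(new_atoms, residues, bonds, angles, dihedrals)


@dataclass
class Trajectory:
    """Ordered coordinate frames (Å) with times (ps) for a fixed topology."""

    topology: Topology
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # (n_frames,), ps, strictly increasing

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValidationError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValidationError("every frame must have one coordinate triple per atom")
        if self.frames.shape[0] != self.times.shape[0]:
            raise ValidationError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class ComplexDefinition:
    """Disjoint receptor/ligand atom index sets covering the whole topology."""

    receptor_atoms: frozenset[int]
    ligand_atoms: frozenset[int]

    @property
    def receptor_index(self) -> np.ndarray:
        return np.array(sorted(self.receptor_atoms), dtype=int)

    @property
    def ligand_index(self) -> np.ndarray:
        return np.array(sorted(self.ligand_atoms), dtype=int)


def validate_complex(topology: Topology, cdef: ComplexDefinition) -> ComplexDefinition:
    """Check that the receptor/ligand partition covers the topology exactly.

    Returns ``cdef`` unchanged when valid; raises :class:`ValidationError`
    naming the offending atom indices otherwise.
    """
    if topology.n_atoms == 0:
        raise ValidationError("empty topology")
    rec, lig = set(cdef.receptor_atoms), set(cdef.ligand_atoms)
    if not rec or not lig:
        raise ValidationError("receptor and ligand sets must both be nonempty")
    shared = sorted(rec & lig)
    if shared:
        raise ValidationError(f"atoms assigned to both receptor and ligand: {shared}")
    missing = sorted(set(range(topology.n_atoms)) - rec - lig)
    if missing:
        raise ValidationError(f"atoms assigned to neither receptor nor ligand: {missing}")
    extra = sorted((rec | lig) - set(range(topology.n_atoms)))
    if extra:
        raise ValidationError(f"atom indices out of range: {extra}")
    return cdef


@dataclass
class EnergyComponents:
    """One snapshot's binding-energy components (kcal/mol)."""

    e_ele: float
    e_vdw: float
    g_polar: float
    g_sa: float
    solvent_model: str  # "GB" or "PB"
    solute_dielectric: int = 1

    def __post_init__(self) -> None:
        if self.solute_dielectric not in (1, 2, 4):
            raise ValidationError("solute_dielectric must be 1, 2 or 4")
        if self.solvent_model not in ("GB", "PB"):
            raise ValidationError("solvent_model must be 'GB' or 'PB'")

    @property
    def effective_total(self) -> float:
        return self.e_ele + self.e_vdw + self.g_polar + self.g_sa


_COMPONENT_KEYS = ("e_ele", "e_vdw", "g_polar", "g_sa")


@dataclass
class BindingEnergyReport:
    """Ensemble means ± SE of all components and the assembled ΔG_bind.

    ``g_binding`` always equals the sum of the component means plus
    ``minus_t_delta_s`` (the −TΔS entropy term; 0.0 when entropy was not
    computed). SE = sample standard deviation / √N.
    """

    solvent_model: str
    solute_dielectric: int
    mean: dict[str, float]
    se: dict[str, float]
    minus_t_delta_s: float
    minus_t_delta_s_se: float
    n_snapshots: int
    entropy_included: bool = True

    def __post_init__(self) -> None:
        if self.n_snapshots < 1:
            raise ValidationError("n_snapshots must be >= 1")
        for k, v in self.se.items():
            if v < 0:
                raise ValidationError(f"SE[{k}] must be >= 0")
        if self.minus_t_delta_s_se < 0:
            raise ValidationError("entropy SE must be >= 0")

    @property
    def g_binding(self) -> float:
        return sum(self.mean[k] for k in _COMPONENT_KEYS) + self.minus_t_delta_s

    @property
    def effective_total(self) -> float:
        """ΔG_bind without the entropy term ("effective binding energy")."""
        return sum(self.mean[k] for k in _COMPONENT_KEYS)

    def to_frame(self) -> pd.DataFrame:
        rows = {k: (self.mean[k], self.se[k]) for k in _COMPONENT_KEYS}
        rows["minus_TdS"] = (self.minus_t_delta_s, self.minus_t_delta_s_se)
        rows["g_binding"] = (self.g_binding, float("nan"))
        return pd.DataFrame(rows, index=["mean", "se"]).T


@dataclass
class ResidueEnergyTable:
    """Per-residue decomposition of the effective binding energy.

    ``table`` is indexed by residue label with columns
    ele / vdw / polar / nonpolar / total (kcal/mol); the column sums equal
    the effective binding energy of the same snapshots.
    """

    table: pd.DataFrame

    @property
    def total(self) -> float:
        return float(self.table["total"].sum())

    def significant_changes(self, other: "ResidueEnergyTable",
                            threshold: float = 1.00) -> pd.DataFrame:
        """Residues whose total contribution differs by more than ``threshold``.

        The reporting filter used when comparing a wild-type table with a
        mutant table (default 1.00 kcal/mol).
        """
        joined = self.table[["total"]].join(other.table[["total"]],
                                            lsuffix="_a", rsuffix="_b", how="outer").fillna(0.0)
        joined["difference"] = joined["total_b"] - joined["total_a"]
        return joined[joined["difference"].abs() > threshold]


@dataclass(frozen=True)
class AlaScanResult:
    """ΔΔG_bind = ΔG_bind(mutant) − ΔG_bind(WT) for one alanine truncation."""

    residue_label: str
    ddg_bind: float
    is_hotspot: bool

    @staticmethod
    def from_ddg(label: str, ddg: float, threshold: float = 2.00) -> "AlaScanResult":
        return AlaScanResult(label, ddg, ddg > threshold)
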