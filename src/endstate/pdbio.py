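"""PDB and parameter-table readers/writers.

The PDB dialect is the fixed-column ATOM/HETATM subset (serial, name,
resName, chainID, resSeq, x, y, z, element); multi-model files map to
:class:`~endstate.core.Trajectory` frames.  Parsing is strict: a malformed
record raises :class:`PdbParseError` carrying the line number.  Residue
numbering is 1-based on disk (PDB convention) and 0-based in memory; the
conversion lives entirely in this module.

Physical parameters travel in a separate tab-delimited table (one record
per atom type: residue name, atom name, element, charge, Rmin/2, ε, radius,
LCPO P1–P4) and are attached to a parsed skeleton in a second pass; atoms
without a matching record are collected in a completeness report.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .core import Atom, Residue, Topology, Trajectory
from .params import ELEMENT_PARAMS


class PdbParseError(ValueError):
    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def write_pdb(topology: Topology, frames: np.ndarray, path: str | Path,
              remarks: list[str] | None = None) -> Path:
    """Write single- or multi-model PDB (occupancy 1.00, B-factor 0.00)."""
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    path = Path(path)
    with path.open("w") as fh:
        for r in remarks or []:
            fh.write(f"REMARK   1 {r}\n")
        multi = frames.shape[0] > 1
        for m, coords in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for a, xyz in zip(topology.atoms, coords):
                res = topology.residues[a.residue_index]
                resseq = _resseq(res)
                name = f" {a.name:<3s}" if len(a.name) < 4 else a.name[:4]
                fh.write(f"ATOM  {a.serial:5d} {name}{'':1s}{res.name:>3s} "
                         f"{a.chain_id[:1]}{resseq:4d}    "
                         f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                         f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


def _resseq(res: Residue) -> int:
    # labels look like "A:SER6"; fall back to span order
    tail = "".join(ch for ch in res.label.split(":")[-1] if ch.isdigit())
    return int(tail) if tail else 1


def read_structure(path: str | Path, dt_ps: float = 10.0
                   ) -> tuple[Topology, np.ndarray | Trajectory]:
    """Parse a PDB file → (topology skeleton, coords or Trajectory).

    The skeleton carries names, elements, chains and residue spans with
    default physical parameters; attach real parameters with
    :func:`attach_parameters`.  Multi-model files become a Trajectory with
    frame times ``dt_ps · (1..n)``.
    """
    path = Path(path)
    models: list[list[tuple]] = []
    current: list[tuple] = []
    seen_model = False
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            seen_model = True
            if current:
                models.append(current)
                current = []
        elif rec == "ENDMDL":
            models.append(current)
            current = []
        elif rec in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                raise PdbParseError(line_no, "truncated ATOM/HETATM record")
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21].strip() or "A"
                resseq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise PdbParseError(line_no, f"malformed field: {exc}") from exc
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = name[0]
            current.append((serial, name, resname, chain, resseq, x, y, z, element))
    if current:
        models.append(current)
    if not models or not models[0]:
        raise PdbParseError(0, "no ATOM/HETATM records found")

    first = models[0]
    atoms: list[Atom] = []
    residues: list[Residue] = []
    prev_key = None
    for serial, name, resname, chain, resseq, *_xyz, element in first:
        key = (chain, resseq, resname)
        if key != prev_key:
            if residues:
                residues[-1] = replace(residues[-1], stop=len(atoms))
            residues.append(Residue(resname, f"{chain}:{resname}{resseq}",
                                    len(atoms), len(atoms)))
            prev_key = key
        rh, eps, rad, mass = ELEMENT_PARAMS.get(element, (1.7, 0.1, 1.5, 12.011))
        atoms.append(Atom(serial=serial, name=name, element=element,
                          residue_index=len(residues) - 1, chain_id=chain,
                          charge=0.0, lj_rmin_half=rh, lj_epsilon=eps,
                          intrinsic_radius=rad, mass=mass))
    residues[-1] = replace(residues[-1], stop=len(atoms))
    topology = Topology(atoms, residues)

    def model_coords(m):
        if len(m) != len(atoms):
            raise PdbParseError(0, "inconsistent atom counts between models")
        return np.array([[rec[5], rec[6], rec[7]] for rec in m])

    if seen_model and len(models) > 1:
        frames = np.stack([model_coords(m) for m in models])
        times = dt_ps * np.arange(1, len(models) + 1)
        return topology, Trajectory(topology, frames, times)
    return topology, model_coords(first)


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------

_PARAM_HEADER = ("residue", "atom", "element", "charge", "rmin_half",
                 "epsilon", "radius", "p1", "p2", "p3", "p4")


def write_parameter_table(topology: Topology, path: str | Path) -> Path:
    """One record per distinct (residue name, atom name) pair."""
    path = Path(path)
    seen = set()
    with path.open("w") as fh:
        fh.write("\t".join(_PARAM_HEADER) + "\n")
        for a in topology.atoms:
            res = topology.residues[a.residue_index]
            key = (res.name, a.name)
            if key in seen:
                continue
            seen.add(key)
            p = a.lcpo_params or (0.0, 0.0, 0.0, 0.0)
            fh.write(f"{res.name}\t{a.name}\t{a.element}\t{a.charge:.6f}\t"
                     f"{a.lj_rmin_half:.4f}\t{a.lj_epsilon:.4f}\t"
                     f"{a.intrinsic_radius:.4f}\t"
                     f"{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\t{p[3]:.6f}\n")
    return path


def read_parameter_table(path: str | Path) -> dict[tuple[str, str], dict]:
    table = {}
    lines = Path(path).read_text().splitlines()
    for line_no, line in enumerate(lines, start=1):
        if line_no == 1 or not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != len(_PARAM_HEADER):
            raise PdbParseError(line_no, "parameter record has wrong field count")
        res, atom, el = parts[0], parts[1], parts[2]
        vals = [float(v) for v in parts[3:]]
        table[(res, atom)] = {
            "element": el, "charge": vals[0], "lj_rmin_half": vals[1],
            "lj_epsilon": vals[2], "intrinsic_radius": vals[3],
            "lcpo_params": tuple(vals[4:8]),
        }
    return table


@dataclass
class CompletenessReport:
    unmatched: list[str]

    @property
    def complete(self) -> bool:
        return not self.unmatched


def attach_parameters(topology: Topology, table: dict[tuple[str, str], dict]
                      ) -> tuple[Topology, CompletenessReport]:
    """Second-pass parameter attachment by (residue name, atom name)."""
    atoms = []
    unmatched = []
    for a in topology.atoms:
        res = topology.residues[a.residue_index]
        rec = table.get((res.name, a.name))
        if rec is None:
            unmatched.append(f"{res.label}:{a.name}")
            atoms.append(a)
            continue
        _, _, _, mass = ELEMENT_PARAMS.get(rec["element"], (0, 0, 0, a.mass))
        atoms.append(replace(a, element=rec["element"], charge=rec["charge"],
                             lj_rmin_half=rec["lj_rmin_half"],
                             lj_epsilon=rec["lj_epsilon"],
                             intrinsic_radius=rec["intrinsic_radius"],
                             lcpo_params=rec["lcpo_params"], mass=mass))
    new = Topology(atoms, topology.residues, topology.bonds, topology.angles,
                   topology.dihedrals)
    return new, CompletenessReport(unmatched)


# bond-length cutoffs (Å) for distance-based bond inference on read
_BOND_CUTOFF = {("H",): 1.3}


def infer_bonds(topology: Topology, coords: np.ndarray,
                heavy_cutoff: float = 1.9, h_cutoff: float = 1.3) -> list[tuple[int, int]]:
    """Distance-based bond detection for PDB input without connectivity."""
    x = np.asarray(coords, float)
    n = topology.n_atoms
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            cut = h_cutoff if "H" in (topology.atoms[i].element,
                                      topology.atoms[j].element) else heavy_cutoff
            if np.linalg.norm(x[i] - x[j]) < cut:
                pairs.append((i, j))
    return pairs


def load_system(pdb_path: str | Path, params_path: str | Path,
                dt_ps: float = 10.0):
    """PDB + parameter table → (topology with bonds, coords or Trajectory).

    Bonds are inferred by distance from the first frame and bonded
    equilibria are set to that frame's geometry (sufficient for every
    end-state analysis; the normal-mode entropy route should be fed a
    generator-built topology whose bonded terms are authoritative).
    """
    from .synthetic import assemble

    skeleton, payload = read_structure(pdb_path, dt_ps)
    table = read_parameter_table(params_path)
    topology, report = attach_parameters(skeleton, table)
    first = payload.frames[0] if isinstance(payload, Trajectory) else payload
    bond_pairs = infer_bonds(topology, first)
    records = [(a.name, a.element, a.charge, a.chain_id, a.residue_index, "")
               for a in topology.atoms]
    spans = [(r.name, r.label, r.start, r.stop) for r in topology.residues]
    full = assemble(records, bond_pairs, np.asarray(first, float), spans)
    # assemble() rebuilds parameters from the element table; reattach the
    # per-atom values from the parameter file (authoritative)
    full, _ = attach_parameters(full, table)
    if isinstance(payload, Trajectory):
        payload = Trajectory(full, payload.frames, payload.times)
    return full, payload, report
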