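"""Orchestration of the end-state binding free-energy workflow.

For an ensemble of snapshots taken from a single complex trajectory this
module computes the per-snapshot components

    ΔE_ele, ΔE_vdw   — intermolecular molecular-mechanics sums
    ΔG_polar         — GB or PB polar solvation of complex − receptor − ligand
    ΔG_SA            — γ·ΔA + β over the LCPO surface-area change

assembles ensemble means with standard errors (SE = STD/√N), adds the
normal-mode −TΔS when supplied, and derives the two follow-up analyses:
per-residue decomposition of the effective (entropy-free) binding energy
and computational alanine scanning (ΔΔG_bind on unchanged snapshots,
hot spot ⇔ ΔΔG > 2.00 kcal/mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (BindingEnergyReport, ComplexDefinition, EnergyComponents,
                   ResidueEnergyTable, AlaScanResult, Topology, Trajectory,
                   validate_complex)
from .forcefield import DielectricModel, coulomb_energy, lj_energy
from .gbsa import (GB_SASA, PB_SASA, GBSettings, SasaSettings, gb_polar_energy,
                   gb_polar_energy_pairwise, lcpo_sasa, nonpolar_energy)
from .nma import BindingEntropyResult
from .pb import PBGrid, pb_polar_energy
from .synthetic import make_mutant

HOTSPOT_THRESHOLD = 2.00  # kcal/mol
INTERFACE_CUTOFF = 8.0  # Å
NONSCANNABLE = ("GLY", "PRO")


@dataclass(frozen=True)
class SnapshotPlan:
    """Even extraction of snapshots: stride ``interval_ps`` over ``span_ps``.

    The first snapshot falls one stride after the span start, so a 10 ns
    span yields 500 snapshots at 20 ps intervals and 125 at 80 ps.
    """

    span_ps: float
    interval_ps: float

    def __post_init__(self) -> None:
        if self.span_ps <= 0 or self.interval_ps <= 0:
            raise ValueError("span and interval must be positive")
        if self.interval_ps > self.span_ps:
            raise ValueError("interval exceeds span")

    @property
    def expected_count(self) -> int:
        return int(math.floor(self.span_ps / self.interval_ps + 1e-9))


def extract_snapshots(traj: Trajectory, plan: SnapshotPlan,
                      start_ps: float | None = None) -> list[np.ndarray]:
    """Evenly strided frames; the count always equals ``plan.expected_count``."""
    times = traj.times
    if len(times) > 1:
        dt = float(times[1] - times[0])
        if abs(plan.interval_ps / dt - round(plan.interval_ps / dt)) > 1e-9:
            raise ValueError("trajectory frame spacing must divide interval_ps")
    if start_ps is None:
        start_ps = float(times[0]) - (float(times[1] - times[0]) if len(times) > 1
                                      else plan.interval_ps)
    end = start_ps + plan.span_ps
    if end > times[-1] + 1e-9:
        raise ValueError(f"span [{start_ps}, {end}] ps exceeds the trajectory "
                         f"(last frame {times[-1]} ps)")
    wanted = start_ps + plan.interval_ps * np.arange(1, plan.expected_count + 1)
    out = []
    for t in wanted:
        idx = int(np.argmin(np.abs(times - t)))
        if abs(times[idx] - t) > 1e-6:
            raise ValueError(f"no frame at {t} ps")
        out.append(traj.frames[idx])
    return out


@dataclass(frozen=True)
class EndstateSettings:
    """Knobs shared by all end-state energies."""

    solute_dielectric: int = 1
    gb: GBSettings = GBSettings()
    pb_grid: PBGrid = PBGrid()
    gb_sasa: SasaSettings = GB_SASA
    pb_sasa: SasaSettings = PB_SASA

    def sasa_for(self, solvent_model: str) -> SasaSettings:
        return self.gb_sasa if solvent_model == "GB" else self.pb_sasa


def _with_dielectric(settings: EndstateSettings) -> GBSettings:
    if settings.gb.solute_dielectric == settings.solute_dielectric:
        return settings.gb
    return GBSettings(solute_dielectric=settings.solute_dielectric,
                      solvent_dielectric=settings.gb.solvent_dielectric,
                      offset=settings.gb.offset, screen=settings.gb.screen)


def snapshot_components(topology: Topology, coords: np.ndarray,
                        cdef: ComplexDefinition, solvent_model: str = "GB",
                        settings: EndstateSettings = EndstateSettings()
                        ) -> EnergyComponents:
    """One snapshot's ΔE_ele, ΔE_vdw, ΔG_polar, ΔG_SA (kcal/mol).

    Under the single-trajectory convention the molecular-mechanics terms are
    pure intermolecular sums (internal terms cancel exactly); solvation
    terms are complex − receptor − ligand on the same coordinates.
    """
    validate_complex(topology, cdef)
    rec, lig = cdef.receptor_index, cdef.ligand_index
    eps = settings.solute_dielectric
    e_ele = coulomb_energy(topology, coords, rec, lig, DielectricModel.constant(eps))
    e_vdw = lj_energy(topology, coords, rec, lig)

    if solvent_model == "GB":
        gb = _with_dielectric(settings)
        g_c = gb_polar_energy(topology, coords, gb)
        g_r = gb_polar_energy(topology, coords, gb, indices=rec)
        g_l = gb_polar_energy(topology, coords, gb, indices=lig)
    elif solvent_model == "PB":
        grid = settings.pb_grid
        eo = settings.gb.solvent_dielectric
        g_c = pb_polar_energy(topology, coords, eps, eo, grid)
        g_r = pb_polar_energy(topology, coords, eps, eo, grid, indices=rec)
        g_l = pb_polar_energy(topology, coords, eps, eo, grid, indices=lig)
    else:
        raise ValueError("solvent_model must be 'GB' or 'PB'")
    g_polar = g_c - g_r - g_l

    sasa = settings.sasa_for(solvent_model)
    _, a_c = lcpo_sasa(topology, coords, sasa)
    _, a_r = lcpo_sasa(topology, coords, sasa, indices=rec)
    _, a_l = lcpo_sasa(topology, coords, sasa, indices=lig)
    g_sa = nonpolar_energy(a_c - a_r - a_l, sasa.gamma, sasa.beta)

    return EnergyComponents(e_ele, e_vdw, g_polar, g_sa, solvent_model, eps)


def assemble_report(components: list[EnergyComponents],
                    entropy: BindingEntropyResult | None = None
                    ) -> BindingEnergyReport:
    """Ensemble means ± SE and the assembled ΔG_bind, report-table shaped."""
    if not components:
        raise ValueError("need at least one snapshot")
    model = components[0].solvent_model
    eps = components[0].solute_dielectric
    arrays = {k: np.array([getattr(c, k) for c in components])
              for k in ("e_ele", "e_vdw", "g_polar", "g_sa")}
    n = len(components)
    mean = {k: float(v.mean()) for k, v in arrays.items()}
    se = {k: (0.0 if n == 1 else float(np.std(v, ddof=1) / np.sqrt(n)))
          for k, v in arrays.items()}
    return BindingEnergyReport(
        solvent_model=model, solute_dielectric=eps, mean=mean, se=se,
        minus_t_delta_s=0.0 if entropy is None else entropy.minus_t_delta_s,
        minus_t_delta_s_se=0.0 if entropy is None else entropy.se,
        n_snapshots=n, entropy_included=entropy is not None)


def binding_free_energy(topology: Topology, snapshots: list[np.ndarray],
                        cdef: ComplexDefinition, solvent_model: str = "GB",
                        settings: EndstateSettings = EndstateSettings(),
                        entropy: BindingEntropyResult | None = None
                        ) -> BindingEnergyReport:
    comps = [snapshot_components(topology, s, cdef, solvent_model, settings)
             for s in snapshots]
    return assemble_report(comps, entropy)


# ---------------------------------------------------------------------------
# per-residue decomposition (GB polar model; pair terms split ½:½)
# ---------------------------------------------------------------------------

def per_residue_decomposition(topology: Topology, snapshots: list[np.ndarray],
                              cdef: ComplexDefinition,
                              settings: EndstateSettings = EndstateSettings()
                              ) -> ResidueEnergyTable:
    """Decompose the effective binding energy into residue contributions.

    Pairwise energies are split ½:½ between the two residues of each pair;
    per-atom GB self terms and surface-area terms go to their own residue.
    The polar model is GB (grid PB is not pairwise-decomposable); the table
    sums to the GB effective binding energy of the same snapshots.
    """
    validate_complex(topology, cdef)
    rec, lig = cdef.receptor_index, cdef.ligand_index
    gb = _with_dielectric(settings)
    sasa = settings.gb_sasa
    eps = settings.solute_dielectric
    n_res = len(topology.residues)
    res_of = np.empty(topology.n_atoms, dtype=int)
    for ridx, r in enumerate(topology.residues):
        res_of[r.start:r.stop] = ridx

    acc = np.zeros((n_res, 4))  # ele, vdw, polar, nonpolar
    from .constants import COULOMB_K

    q = topology.charges
    rh, ep = topology.lj_rmin_half, topology.lj_epsilon
    for coords in snapshots:
        x = np.asarray(coords, float)
        d = x[rec][:, None, :] - x[lig][None, :, :]
        r = np.sqrt(np.sum(d * d, axis=-1))
        e_pair = COULOMB_K * np.outer(q[rec], q[lig]) / (eps * r)
        s6 = ((rh[rec][:, None] + rh[lig][None, :]) / r) ** 6
        v_pair = np.sqrt(np.outer(ep[rec], ep[lig])) * (s6 * s6 - 2.0 * s6)
        half_e_rec = 0.5 * e_pair.sum(axis=1)
        half_e_lig = 0.5 * e_pair.sum(axis=0)
        half_v_rec = 0.5 * v_pair.sum(axis=1)
        half_v_lig = 0.5 * v_pair.sum(axis=0)
        np.add.at(acc[:, 0], res_of[rec], half_e_rec)
        np.add.at(acc[:, 0], res_of[lig], half_e_lig)
        np.add.at(acc[:, 1], res_of[rec], half_v_rec)
        np.add.at(acc[:, 1], res_of[lig], half_v_lig)

        # GB polar: per-atom row sums give the ½:½ split automatically
        m_c = gb_polar_energy_pairwise(topology, x, gb)
        atom_polar = m_c.sum(axis=1)
        m_r = gb_polar_energy_pairwise(topology, x, gb, indices=rec)
        atom_polar[rec] -= m_r.sum(axis=1)
        m_l = gb_polar_energy_pairwise(topology, x, gb, indices=lig)
        atom_polar[lig] -= m_l.sum(axis=1)
        np.add.at(acc[:, 2], res_of, atom_polar)

        a_c, _ = lcpo_sasa(topology, x, sasa)
        a_r, _ = lcpo_sasa(topology, x, sasa, indices=rec)
        a_l, _ = lcpo_sasa(topology, x, sasa, indices=lig)
        delta_a = a_c.copy()
        delta_a[rec] -= a_r
        delta_a[lig] -= a_l
        np.add.at(acc[:, 3], res_of, sasa.gamma * delta_a)

    acc /= len(snapshots)
    labels = [r.label for r in topology.residues]
    df = pd.DataFrame(acc, index=labels, columns=["ele", "vdw", "polar", "nonpolar"])
    df["total"] = df.sum(axis=1)
    return ResidueEnergyTable(df)


# ---------------------------------------------------------------------------
# computational alanine scanning
# ---------------------------------------------------------------------------

def interface_residues(topology: Topology, coords: np.ndarray,
                       cdef: ComplexDefinition,
                       cutoff: float = INTERFACE_CUTOFF) -> list[str]:
    """Labels of residues with any atom within ``cutoff`` of the partner."""
    x = np.asarray(coords, float)
    rec, lig = cdef.receptor_index, cdef.ligand_index
    d = np.sqrt(np.sum((x[rec][:, None, :] - x[lig][None, :, :]) ** 2, axis=-1))
    near_rec = rec[np.any(d < cutoff, axis=1)]
    near_lig = lig[np.any(d < cutoff, axis=0)]
    labels = []
    for r in topology.residues:
        if any(r.start <= i < r.stop for i in np.concatenate([near_rec, near_lig])):
            labels.append(r.label)
    return labels


def _truncate_to_alanine(topology: Topology, snapshots: list[np.ndarray],
                         label: str) -> tuple[Topology, list[np.ndarray]]:
    """Mutant topology + per-frame coordinates for one alanine truncation."""
    mut_top, _ = make_mutant(topology, snapshots[0], label, "truncate")
    frames = []
    for s in snapshots:
        _, xyz = make_mutant(topology, s, label, "truncate")
        frames.append(xyz)
    return mut_top, frames


def alanine_scan(topology: Topology, snapshots: list[np.ndarray],
                 cdef: ComplexDefinition,
                 residues: list[str] | None = None,
                 settings: EndstateSettings = EndstateSettings(),
                 cutoff: float = INTERFACE_CUTOFF,
                 hotspot_threshold: float = HOTSPOT_THRESHOLD
                 ) -> list[AlaScanResult]:
    """ΔΔG_bind per residue from truncating its side chain to a methyl.

    Each candidate (auto-built: any non-Gly/Pro residue within ``cutoff`` of
    the partner molecule) is truncated at Cβ and the effective binding
    energy recomputed on the *same* snapshots; ΔΔG = ΔG(mutant) − ΔG(WT),
    entropy omitted from both.  Explicitly requesting a glycine or proline
    residue raises.
    """
    validate_complex(topology, cdef)
    if residues is None:
        residues = [lab for lab in interface_residues(topology, snapshots[0],
                                                      cdef, cutoff)
                    if topology.residue_by_label(lab).name not in NONSCANNABLE]
    else:
        bad = [lab for lab in residues
               if topology.residue_by_label(lab).name in NONSCANNABLE]
        if bad:
            raise ValueError(
                f"glycine/proline residues cannot be alanine-scanned: {bad}")

    wt = binding_free_energy(topology, snapshots, cdef, "GB", settings)
    results = []
    rec_set = set(int(i) for i in cdef.receptor_index)
    for lab in residues:
        mut_top, mut_frames = _truncate_to_alanine(topology, snapshots, lab)
        # rebuild the partition for the (possibly different) atom count
        n_rec = sum(1 for a in mut_top.atoms if a.chain_id
                    == topology.atoms[min(rec_set)].chain_id)
        mut_cdef = ComplexDefinition(frozenset(range(n_rec)),
                                     frozenset(range(n_rec, mut_top.n_atoms)))
        mut = binding_free_energy(mut_top, mut_frames, mut_cdef, "GB", settings)
        ddg = mut.effective_total - wt.effective_total
        results.append(AlaScanResult.from_ddg(lab, ddg, hotspot_threshold))
    return results


def report_to_text(report: BindingEnergyReport) -> str:
    """Render the standard component table as delimited text (2-decimal display)."""
    rows = [f"# solvent_model={report.solvent_model} "
            f"solute_dielectric={report.solute_dielectric} "
            f"n_snapshots={report.n_snapshots}",
            "component\tmean\tse"]
    labels = {"e_ele": "dE_ele", "e_vdw": "dE_vdw", "g_polar": "dG_polar",
              "g_sa": "dG_SA"}
    for k, lab in labels.items():
        rows.append(f"{lab}\t{report.mean[k]:.2f}\t{report.se[k]:.2f}")
    rows.append(f"-TdS\t{report.minus_t_delta_s:.2f}\t{report.minus_t_delta_s_se:.2f}")
    rows.append(f"dG_binding\t{report.g_binding:.2f}\t")
    return "\n".join(rows) + "\n"
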