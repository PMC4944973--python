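# Methods

`endstate` implements single-trajectory end-state binding free-energy
analysis (MM-GB/PBSA) together with the trajectory analytics that usually
accompany it (RMSD/RMSF, Cα-covariance PCA with porcupine export, a
three-atom rigid-rotation angle, an OH-π interaction detector), a
normal-mode entropy route, per-residue decomposition and computational
alanine scanning.  It operates on synthetic toy complexes generated by the
package itself, so every stage is testable without downloads or an MD
engine.

## The end-state model

For a receptor–ligand complex sampled by a single trajectory, the binding
free energy is assembled per snapshot and averaged:

    ΔG_bind = ⟨ΔE_ele⟩ + ⟨ΔE_vdw⟩ + ⟨ΔG_polar⟩ + ⟨ΔG_SA⟩ + (−TΔS)

* **ΔE_ele, ΔE_vdw** — intermolecular Coulomb and 12-6 Lennard-Jones sums
  over all receptor×ligand pairs (no cutoff).  Under the single-trajectory
  convention the intramolecular (bonded + internal nonbonded) terms cancel
  exactly between complex, receptor and ligand; this identity is asserted
  in the tests.  Coulomb constant 332.0637 kcal·Å/(mol·e²); harmonic terms
  use the Amber convention E = k(r−b₀)² (no ½); 1-4 pairs are scaled by
  1/1.2 (electrostatics) and 1/2 (van der Waals).
* **ΔG_polar** — GB or PB polar solvation of complex − receptor − ligand,
  all evaluated on the same frame.
* **ΔG_SA** — γ·ΔA + β over the LCPO surface-area change, with
  γ/β = 0.0072/0 kcal/mol/Å² for the GB branch and 0.00542/0.92 for the PB
  branch.
* **−TΔS** — rigid-rotor/harmonic-oscillator entropy from normal modes
  (below), T = 300 K by default (the usual MD thermostat setting).

Standard errors are SE = sample standard deviation / √N over snapshots.
The default snapshot plans are 500 frames at 20 ps intervals over a 10 ns
span for the energy terms and 125 frames at 80 ps for the entropy (it is
far more expensive per frame).

### Generalized Born

Pairwise-descreening ("HCT"-type) effective radii: every intrinsic radius
is reduced by a fixed offset (0.09 Å), then descreened by the analytic
sphere integral of the Coulomb-field approximation over each neighbour,
scaled by a per-element factor (H 0.85, C 0.72, N 0.79, O 0.85, S 0.96,
P 0.86).  The polar energy is Still's combining function with self terms,
which reproduces the analytic Born ion exactly for an isolated charge.
The pairwise HCT integral was verified against Monte-Carlo quadrature of
the same Coulomb-field approximation (0.02 % on an overlapping pair).  No
claim is made that these parameters reproduce any particular Amber `igb`
variant numerically; the model is documented here and is the package's GB.

### Poisson–Boltzmann

Linearized PB at zero ionic strength on a uniform grid (7-point stencil).
The dielectric lives on grid edges: each edge takes a harmonic mean of
solute/solvent dielectric weighted by the fraction of the edge inside the
van der Waals surface (intrinsic radii, no probe) — this fractional
smoothing is what brings the Born-ion error to ~0.3 % at 0.25 Å spacing.
Charges are spread trilinearly; the boundary condition is the solvent-
screened Coulomb monopole sum; the linear system is solved by conjugate
gradients to a relative residual of 1e-6.  Energies use a two-solve
reference scheme (a second solve with ε_out = ε_in) so the grid
self-energy cancels identically.  Validated against the Born ion and the
Kirkwood multipole series for a dipole in a sphere (0.2 % at 0.25 Å).

### LCPO surface area

A_i = P1·S1 + P2·ΣA_ij + P3·ΣA_jk + P4·Σ A_ij·ΣA_jk over geometric
neighbours, probe radius 1.4 Å, hydrogens carry zero area, per-atom areas
clamped at ≥ 0.  The P1..P4 table shipped as package data is keyed by
element and bonded-heavy-neighbour count and was calibrated by weighted
least squares against the package's own Monte-Carlo SASA reference on
randomized bonded clusters pooled with atoms harvested from generated toy
dimers.  Quaternary carbon is assigned all-zero coefficients (buried by
convention).  Held-out accuracy: 3–5-atom toys within ~6 %, and the
buried-interface ΔA of a contacting dimer is negative and tracks the
Monte-Carlo value.  Known bias: a near-isolated bonded pair is ~7 % high.
The table is plain TSV and can be replaced wholesale for other regimes.

### Normal-mode entropy

Each snapshot's complex, receptor and ligand are minimized independently
in a distance-dependent dielectric ε(r) = 4r (L-BFGS with the analytic
gradient, up to 10000 steps, target gradient RMS < 0.001 kcal/mol/Å,
followed by Newton polishing with the pseudo-inverse Hessian to ~1e-10 so
the spectrum does not depend on where the line search stopped).  The
Hessian is built by central differences of the analytic gradient and
symmetrized; global rigid-body modes are projected out of the
mass-weighted Hessian before diagonalization.  Near-zero modes
(|ν| < 1 cm⁻¹) are dropped and counted: a minimized nonlinear molecule has
exactly six, a diatomic five, and a dissociated dimer twelve (the six
relative rigid-body motions are genuine zeros at infinite separation).
Imaginary frequencies above the threshold are recorded as warnings and
excluded.  S_trans is Sackur–Tetrode at 1 atm, S_rot the classical rigid
rotor from the principal moments (symmetry number 1 — proteins are
asymmetric), S_vib the quantum harmonic oscillator per mode.

On the shipped toy complexes (tens of atoms) the −TΔS association penalty
(~20 kcal/mol) exceeds the small effective binding energy, so the full
ΔG_bind is positive; the pipeline's purpose at toy scale is exercising the
identities and directions, not predicting affinities.

### Per-residue decomposition and alanine scanning

Decomposition apportions the *effective* binding energy (no entropy):
intermolecular pair energies split ½:½ between the two residues, per-atom
GB terms by the symmetric row sums of the pairwise GB matrix, per-atom
ΔSASA to its own residue.  The GB polar model is used regardless of which
total is reported, because grid PB is not pairwise-decomposable.  The
table sums to the effective total to 1e-6 kcal/mol by construction, and a
reporting filter marks residues whose wild-type-vs-mutant difference
exceeds 1.00 kcal/mol.

Alanine scanning truncates a side chain at Cβ (the first side-chain atom
past Cβ becomes a hydrogen at 1.09 Å along its old direction, the rest are
deleted, Cβ reset to the alanine archetype) and recomputes the effective
binding energy on the unchanged snapshots: ΔΔG = ΔG(mutant) − ΔG(WT),
entropy omitted from both.  Residues with ΔΔG > 2.00 kcal/mol are hot
spots.  Candidates are auto-selected from an 8 Å interface shell; glycine
and proline are excluded (and explicitly requesting them is an error).
Scanning an alanine is an exact no-op, so its ΔΔG is exactly zero — a
useful calibration of the whole path.

## Trajectory analytics

Superposition is the proper-rotation Kabsch solution (mirror images keep
positive RMSD).  RMSF and PCA superpose all frames onto the *converged*
mean structure (iterated fitting) of the selection — Cα atoms by
convention — and PCA diagonalizes the 3N Cartesian covariance
C_ij = ⟨(x_i−⟨x_i⟩)(x_j−⟨x_j⟩)⟩.  Because fitting removes six rigid-body
degrees of freedom, planted-mode recovery tests must plant *internal*
modes (the generator provides directions orthogonal to the rigid-body
subspace); a planted internal variance is then recovered within a few
percent at 5000 frames.

The rigid-rotation angle is the planar angle at a vertex atom between two
marker atoms, per frame, summarized as mean ± sample (ddof = 1) SD; the
vertex is the caller's middle argument (for the classic three-Cα
construction the physically central residue), and the convention is
documented here because population vs sample SD differ visibly for short
windows.

The OH-π detector computes, per frame, the distance from the hydroxyl H to
the six-ring centroid and the elevation of the O→H vector above the ring's
least-squares plane (90° = perpendicular approach; rings with RMS
out-of-plane deviation > 0.3 Å set a planarity warning).  A frame is
"strong" iff the angle lies in [65°, 90°] and the distance in
[2.0, 3.5] Å; occupancy is the flagged fraction.

## The synthetic-data generator

Toy complexes are two parallel backbone chains (N–CA–C per residue, Cα
spacing 3.8 Å) whose side chains face each other across the interface.
Archetypes: ALA (methyl), GLY (none), LYS (+1 amine), ASP (−1
carboxylate), SER (polar O–H donor), SEP (phosphoserine-like, −2), PHE
(neutral six-ring).  Contact pairs are aligned geometrically: the first
pair sets the inter-chain distance so its side-chain anchors sit `gap` Å
apart (default 2.5 Å), further contacted residues get small individual
x-shifts.  A SER–PHE contact therefore places the hydroxyl H directly
over the ring centroid at the gap distance with a 90° elevation — the
OH-π construction — and LYS–ASP forms a salt bridge.  All joints are bent
(~157°): no three bonded atoms are colinear, because angle gradients are
singular at 180°.

Bonded equilibrium values (b₀, θ₀, torsion phases) are taken from the
built geometry, so the mean structure is an approximate minimum of the
force field — the near-harmonic regime that RMSF/PCA/NMA assume.  The
parameter set (element LJ, modified-Bondi-style radii, masses, archetype
charges) is a compact self-consistent table shipped with the package; it
is deliberately *not* a protein force field.

Trajectories are mean + independent isotropic Gaussian noise + optional
planted collective modes, sampled independently per frame.  What this does
**not** emulate: autocorrelation, anharmonicity, solvent friction,
conformational transitions, or realistic force-field energetics.  Passing
tests therefore demonstrate the estimators and identities (superposition,
covariance recovery, SE scaling, conservation, mutation direction), not
agreement with any experimental or published per-system number — those
depend on long explicit-solvent trajectories that are out of scope here.

Mutations: truncation to alanine, hydroxyl→carboxylate charge swap
(net 0 → −1), and phosphorylation (net −2), each touching only the target
residue; double mutants compose and are order-independent.  Truncating a
planted salt bridge makes ΔG_bind less negative on identical frames — the
qualitative direction expected for interface-charge mutants — and this is
asserted end-to-end.

## Numerical choices and degenerate inputs

* Hessians: central differences of the analytic gradient (step 1e-5 Å),
  symmetrized; validated against second differences of the energy and
  closed forms.
* PB grids pad symmetrically around the solute bounding box; translation
  by non-integer grid multiples changes the Born energy by ≲ 0.1 %.
* Single-frame trajectories: RMSF returns zeros with a flag; a
  single-snapshot ensemble reports SE = 0 with a flag.
* Static trajectories give zero PCA eigenvalues, not an error; coincident
  angle atoms and rings ≠ 6 atoms are errors.
* Solute dielectric ε ∈ {1, 2, 4}: the headline is ε = 1; when ε > 1 the
  intermolecular Coulomb term and the GB/PB internal dielectric use the
  same value.
* Energies are reported to 2 decimals in text outputs with full precision
  retained internally; all file writers are deterministic under fixed
  config + seed and carry a provenance header (version, config hash,
  seed).

## Problem sizes

The shipped analyses run at toy scale by design: complexes of a few dozen
atoms, ensembles of tens to a few hundred frames for energies, a handful
of frames for NMA entropy, 2000–5000 frames for geometric statistics, and
PB grids of 0.25–0.6 Å spacing.  These sizes exercise every code path and
keep the full validation suite and the reproduction script comfortably
fast on a single CPU.

## Known limitations

* The GB flavour and LCPO coefficients are self-calibrated, documented
  models — not numerical reproductions of any specific Amber variant.
* LCPO overestimates near-isolated bonded pairs by ~7 %.
* The noise model has no autocorrelation, so time-correlation statistics
  (e.g. autocorrelation-aware error bars) are out of scope.
* PB is not decomposable per residue; decomposition always uses GB.
* The alanine-scan partition rebuild assumes the receptor chain's atoms
  precede the ligand chain's (true for all generated systems).
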