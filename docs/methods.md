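# Methods

This note documents the models, defaults, and numerical choices behind
`lolkit`, and what its synthetic fixtures do and do not establish.

## Sequence model

Lipoproteins are recognized purely by the lipobox pattern
`[LVI][ASTVI][GAS][C]`; every matching 4-residue window is reported,
overlaps included, and the caller selects a site (the default prefers a
match whose implied signal peptide is 15–40 residues long, a plausible SP
length, falling back to the first match).  No machine-learned SP
prediction is attempted.  Nonstandard residues (X, U, B, Z...) are
rejected rather than coerced, because the tether builder needs defined
geometry for every residue it models.  All sequence-facing indices are
1-based, matching PDB author numbering so sequence positions cross-
reference structures directly.

Maturation states: `SP` and `SP_DI` keep the full precursor; `DI` and
`TRI` start at the lipobox cysteine (SP cleaved); `UNTETHERED` is a
user-designated core range with no tether or lipid.  The lipid anchor is
implied by the state: diacyl for `SP_DI`/`DI`, triacyl for `TRI`.

## Tether geometry

* **Orientation.**  The folded core is rigidly transformed so the backbone
  positions of its first two residues lie on the *z*-axis with residue 1
  below the backbone centroid — the N terminus points at the membrane, the
  core starts away from it.  The rotation comes from
  `scipy.spatial.transform.Rotation.align_vectors` (proper rotation,
  det = +1); internal geometry is preserved to < 1e−6 Å, and the
  operation is idempotent.
* **SP helix.**  Residues 1 through the lipobox cysteine are built as an
  ideal α-helix — 1.5 Å rise and 100° twist per residue, 2.3 Å Cα radius,
  axis vertical.  These are canonical α-helix values; no tilt is applied
  before membrane insertion.
* **Disordered linker.**  Residues missing between the cysteine and the
  first resolved core residue are modeled as disordered with an
  unstructured length of **3.5 Å per residue**: the cysteine is placed
  n × 3.5 Å straight below the core start, and the intervening residues on
  a seeded, laterally perturbed path relaxed by steepest descent away from
  any core backbone bead closer than 3.0 Å.  Any clash-free conformer
  satisfying the endpoint distance is accepted; the construction is
  deterministic given its seed.  With zero missing residues the cysteine
  (or the core itself) connects at one Cα–Cα virtual-bond spacing
  (3.8 Å).  Linkers beyond 35 residues trigger a warning: at that length
  the disordered span dominates the construct's behaviour.
* **Representation.**  Models are CG-ready: one backbone pseudo-atom per
  modeled tether residue plus side-chain pseudo-atoms from a per-residue
  count table (Martini-style mapping; GLY/ALA none, aromatics 3–4).
  Atomistic tether detail is out of scope.  Coordinates are Å internally;
  the GRO writer emits nm.

## Coarse-grained topologies

Diacylglycerylcysteine is assembled the way the chemistry runs: the
glycerol and both acyl chains of a **POPG** template (the physiological
acyl donor) are retained, its headgroup and phosphate discarded, and a new
bond joins the cysteine side-chain bead to the first glycerol bead.
Triacylation bonds a linear palmitoyl fragment to the cysteine *backbone*
bead (the amide-linked third chain); re-grafting an already-triacylated
topology is an error.  All bonded terms among retained template beads are
preserved verbatim; the two new cross-fragment bonds copy the template's
analogous phosphate–glycerol and tail bonds, since no experimental values
exist for the new linkages in this dialect.  Grafting is a pure function
over immutable topologies.

Templates are data, not code: annotated itp files (a `fragment_role` per
bead) for POPG/POPE/cysteine/palmitoyl in Martini 2.2 and Martini 3
dialects ship with the package.  Bead names follow the published Martini
lipid topologies and bonded values are conventional Martini lipid values;
the files are synthetic template data (see header comments), and the test
suite asserts structural properties — bead counts, connectivity, charge
sums, round-trips — not force-field-exact constants.  Virtual-site
variants of the parameters are out of scope.

The elastic network connects **all and only** core backbone-bead pairs
within 0.7 nm (KD-tree search, verified against the all-pairs oracle).
Modeled tether residues are excluded so the linker stays disordered and
dynamic — the network starts at the first core residue.  The force
constant defaults to 500 kJ mol⁻¹ nm⁻², the conventional Martini elastic-
network value, and is user-configurable.

## System assembly

Lipid counts are apportioned by largest remainder, which preserves leaflet
totals exactly and is deterministic.  A leaflet containing LPS is counted
by area at 1.7 nm² per molecule.  Run-parameter defaults: 20 fs timestep,
323 K / 1 bar with 1.0 and 12.0 ps couplings, 1.1 nm nonbonded cutoff,
neighbour update every 20 steps, 0.15 M NaCl; umbrella runs differ only in
temperature (310 K).  The module writes mdp-dialect files but never
invokes an MD engine.

Umbrella windows are planned at consecutive 0.1 nm targets from zero
center-of-mass separation to the furthest pull distance, each target
taking the nearest trace frame (absolute errors rounded at 1e−12 nm so
representation noise cannot break ties; exact ties go to the earlier
frame).  A target with no frame within half a spacing raises an error
naming the gap.  A 50–80 window count is reported as in or out of range,
not enforced.  The pull force constant is 1000 kJ mol⁻¹ nm⁻².

"Low-mobility" for the restraint triangle is operationalized as lowest
positional RMSF over a supplied equilibration trajectory; the "base" of
the protein defaults to the 20 % of beads with lowest *z*.  Among
candidates, the combination with the smallest fluctuation sum whose
triangle area clears a non-collinearity floor wins, with index-order tie
breaks — fully deterministic.  No protein restraint is applied to
membrane-only umbrella systems by default.

## Contact analysis

A contact is binary per (frame, residue, bead class): any particle of the
residue within 6 Å of any bead of the class, under orthorhombic periodic
minimum-image distances (`MDAnalysis.lib.distances.capped_distance`,
verified against an O(N²) brute-force oracle).  Classes follow PE/PG
headgroup chemistry: GL0 (PG glycerol headgroup), NH3 (PE ethanolamine),
PO4, GL1:2 (ester glycerols), Tail (acyl beads `[CD]#[AB]`).

Replicate reproducibility is the Pearson *r* between per-residue total
contact vectors (classes summed — the footprint that defines a binding
mode); class-resolved correlation is available as an option.
Zero-variance profiles yield missing (NaN) entries, never 0.  Binding
modes are single-linkage groups at r ≥ 0.5 (configurable), i.e. connected
components of the thresholded correlation graph, ordered by size with
index tie-breaks.  The threshold is this package's operationalization of
a qualitative red/blue reproducibility split; it is a declared choice, not
an inference of any published clustering procedure.

Deformation surfaces bin phosphates on a 2 Å xy-grid (configurable),
splitting leaflets by the sign of z relative to the instantaneous
all-phosphate center recomputed each frame.  Empty bins are NaN and
flagged, never zero-filled; bins whose samples sit persistently within
2 Å of the center are flagged as leaflet-ambiguous.  The summary reports
the per-leaflet maximum center-to-phosphate height and a bulk thickness
(median bin thickness beyond a stated radius from the protein, or from
the box center without one).

## WHAM

Self-consistent iteration on shared bins (default one per 0.02 nm over
the sampled range, or an explicit `xrange`), with P renormalized every
iteration and the gauge fixed by F₀ = 0; convergence at max|ΔFᵢ| < 1e−6
kJ/mol, iteration cap 1e5.  Disconnected window histograms raise an error
carrying the adjacent-overlap report; kT uses the common window
temperature (kB = 0.008314462618 kJ mol⁻¹ K⁻¹).  With a single unbiased
window the fixed gauge makes the estimate collapse exactly — bit for
bit — to direct Boltzmann inversion of the shared histogram, which the
tests assert.  No autocorrelation correction is applied; sample counts
enter raw, with the whole-window Bayesian bootstrap (unit-mean
Dirichlet weights over windows, default 200 replicates, seeded) absorbing
within-window correlation.  Convergence is diagnosed by re-estimating on
consecutive time fractions and reporting the largest per-bin deviation
between re-anchored profiles.  Profiles are used as computed — no
symmetrization or truncation before reading off minima.  Extraction free
energies are the mean anchored G over a stated plateau region; a plateau
slope above 5 kJ mol⁻¹ nm⁻¹ attaches a not-converged warning.

## Transfer thermodynamics

Steps are pairwise differences of extraction free energies with the sign
convention *positive = energy the cell must supply*; the net equals
ΔG_IM − ΔG_OM as an exact algebraic identity (asserted at machine
precision).  Per-step errors combine per-profile bootstrap errors in
quadrature when provided.  The ATP budget uses a per-ATP release between
31.55 and 46.5 kJ/mol; a step exceeding the low end but not the high end
of the n-ATP budget is reported as *marginal* rather than a binary call.

## Synthetic fixtures: what they do and do not show

The generators emulate only the statistical and geometric structure each
analysis assumes:

* **Toy structures** plant one lipobox (the random sequence avoids L/V/I/C
  elsewhere, so the planted window is the only match) and withhold
  N-terminal coordinates to exercise the linker rules.  By default the
  cysteine sits at residue 5 when ≥ 5 residues are missing, else at the
  start of the resolved region (zero linker).
* **Membrane trajectories** realize requested per-residue, per-class
  contact counts exactly, via dedicated beads parked out of range except
  in chosen frames; residues are spaced 20 Å so no bead can serve two
  residues.  Replicates of the same ground truth therefore correlate at
  exactly r = 1.
* **Umbrella samples** are drawn by exact rejection sampling from each
  window's biased Boltzmann density: a Gaussian proposal centered on the
  biased mode with the *minimum* curvature of U + w as its precision
  dominates the (log-concave) target rigorously, so accepted samples are
  independent and exactly distributed — estimator tests are free of
  autocorrelation confounds.  For harmonic U the acceptance is
  identically 1.  A bias too weak to convexify the potential, or an
  acceptance rate below 1e−4, raises an error.  Window plans for the
  recovery tests extend beyond the range over which the PMF is read off
  (centers to ±1.0 nm for a ±0.8 nm harmonic readout; ±1.25 nm for a
  ±0.9 nm double-well readout), because steep outer gradients shift each
  window's sampled density inward — the same practice a steered-pull
  protocol follows.
* **Deformed membranes** scatter phosphates on ±field(x, y) sheets with
  mirrored jitter, which keeps the per-frame membrane center exactly on
  the midplane so leaflet splitting is noise-free by construction.

Problem sizes in the test suite and the acceptance script — 10⁵ samples
per window across ~40–50 windows for WHAM recovery, a few thousand
phosphate beads over a handful of frames for surfaces — were chosen as the
smallest sizes at which statistical error sits well below the quantities
being read off.

Passing these tests establishes that the estimators are correct on data
satisfying their assumptions.  It does not establish anything about
Martini membrane physics: real trajectories have correlated frames,
anisotropic deformations, asymmetric leaflets, and force-field-specific
contact statistics.  The absolute extraction free energies of the
cysteine-lipid moiety and the deformation extrema around the LolCDE
transporter require microsecond coarse-grained simulations; this package
computes them from such data but cannot generate the data itself.

## Known limitations

* The linker builder returns one unbiased clash-free conformer, not an
  ensemble; conformational averaging is left to the simulation.
* The itp dialect covers `[moleculetype]/[atoms]/[bonds]/[constraints]/
  [angles]` — dihedrals, exclusions, and virtual sites are not parsed.
* Binding-mode grouping is threshold-sensitive near r ≈ 0.5; the
  threshold is exposed for that reason.
* `lipid_counts` treats an LPS leaflet as single-component.
* Bootstrap errors are per-bin standard deviations; correlations between
  bins are not reported.
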