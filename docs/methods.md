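# Methods

`assdkit` models the computational side of amorphous (salt) solid dispersion
development for a poorly water-soluble drug: screening drug–polymer
miscibility by group contributions, planning supersaturated
drug/oligomer/counterion simulation boxes, and analysing (toy) trajectories
for the structural and energetic signatures of aggregation and its
inhibition by polymeric excipients.  The reference system throughout is
celecoxib (CEL) with the copolymer PVP-VA (6:4 vinylpyrrolidone:vinyl
acetate by mass) and M-grade HPMCAS.

## Group-contribution miscibility screen (`assdkit.gcontrib`)

The Hildebrand solubility parameter is estimated two ways:

* **Fedors**: δ = √(ΔE_v/V_m), with the vaporization energy and molar
  volume accumulated additively over functional groups.
* **Hoftyzer–Van Krevelen (HVK)**: δ² = δ_d² + δ_p² + δ_h² with
  δ_d = ΣF_d/V, δ_p = √(ΣF_p²)/V, δ_h = √(ΣE_h/V).

The polar term follows the root-sum-of-squares form exactly as published.
Note that this form is not homogeneous in the group counts (δ_p of k
repeats of a molecule scales as 1/√k); this is a property of the original
HVK formula, and the package implements it as such rather than the
alternative (ΣF_p)²-style pooling.

Drug–polymer compatibility is summarised by the mean-δ mismatch
Δδ = |δ̄_drug − δ̄_polymer| (mean over the two methods) with the
conventional verdict "miscible" iff Δδ < 7 MPa^1/2 (strict inequality; the
boundary is judged immiscible), and by the Flory–Huggins interaction
parameter

    χ = V_site · Δδ² / (R T),   T = 298.15 K,

with the lattice-site volume V_site taken as the drug's Fedors molar
volume.  That choice is validated internally: inverting the χ definition on
the two reference (Δδ, χ) pairs localizes V_site at 241–244 cm³/mol, which
is exactly the celecoxib Fedors volume the tables produce (242 cm³/mol).

**Coefficient tables and decompositions.**  The aliphatic, olefinic,
aromatic, ether/ester/acid, amine and halogen rows of the shipped table are
the canonical Fedors (1974) and HVK coefficients.  Four entries vary
substantially between published compilations — CF3, the sulfone SO2, the
tertiary (lactam) amide CON<, and the adjacent-diol OH variant used for
carbohydrate backbones.  Because published celecoxib screening values come
with neither a coefficient table nor group assignments, these four entries
were fixed by requiring consistency with the printed reference parameters
(δ_F(CEL) = 23.88, δ_HVK(CEL) = 23.82 MPa^1/2, V_m ≈ 242 cm³/mol, PVP-VA
22.74/22.94); they are data-file
entries, documented per group in `data/group_contributions.csv` and
`data/decompositions.json`, and are not adjusted anywhere in code.  The
celecoxib decomposition counts one methyl, two p-phenylene units, a CF3, the
pyrazole ring atom-by-atom with a 5-ring closure, a sulfone and a primary
amine, and balances the C17H14F3N3O2S formula exactly.  HPMCAS is expressed
as an averaged anhydroglucose repeat unit whose three substituent positions
carry the M-grade proportions (methoxy 64.4%, hydroxypropoxy 8.9%, acetyl
11.1%, succinate 8.9%, free hydroxyl 6.7% of positions), which makes its
group counts fractional; fractional decompositions skip the atom-balance
check.  Copolymers pool repeat-unit group counts mole-proportionally (mass
fraction ÷ unit molar mass) before a single application of the formulas.

Given the acknowledged ambiguity of group assignment, reproduction of the
reference δ values is tested at ±0.3 MPa^1/2 and χ at ±0.01.

## Formulation arithmetic (`assdkit.formulation`)

Plain composition bookkeeping, with reporting precision matching the
reference values (ratios to 2 decimals, supersaturation to 3 significant
figures):

* oligomer mass = Σ count·unit mass + an explicit end-group correction.
  The PVP-VA 34-mer fixture (18 VP + 16 VA) calibrates the correction to
  the published 3375.5 Da (the two-H-terminated raw sum is ≈3378.0 Da; the
  reference model's end groups are unstated).  The HPMCAS 15-mer fixture
  does the same for 3691.5 Da and carries net charge −4 from its ~4
  deprotonated succinates.
* drug:oligomer mass ratio 1:x with x = m_olig/(n_drug·m_drug); counterion
  ratios at 1:1 stoichiometry; supersaturation = (dose/volume)/solubility.
* salt pairs for a target molarity: round(V·c·N_A) with nearest-integer
  rounding.  At exactly 0.01 M this gives 7 pairs for a 106 Å cube and 8
  for a 112 Å cube; the reference composition lists 9 for the 112 Å box,
  which corresponds to ≈0.0102 M — within its stated "~0.01 M".
* electroneutrality: n_Na = |Σ negative solute charges| + salt pairs,
  n_Cl = salt pairs; every emitted box plan is checked to be neutral.
  Water counts are stored verbatim, never predicted (they depend on the
  packing software used to solvate).
* residual-charge redistribution shifts every atomic charge equally so the
  oligomer total hits its target (the correction applied when capped
  monomer charge sets leave a non-integer net charge); differences between
  atoms are preserved exactly.
* random insertion places molecule centres uniformly with a minimum-image
  separation floor, by seeded rejection sampling with a bounded attempt
  budget.

## Trajectory analysis (`assdkit.trajkit`)

Orthorhombic periodic boxes only; all distances are minimum-image.

* **RMSD**: mass-unweighted, after optimal superposition (Kabsch, via
  scipy's `Rotation.align_vectors`).
* **R_g**: mass-weighted about the selection's centre of mass.
* **Equilibration**: default split at the trajectory midpoint (the
  reference trajectories converge after about half the run); an optional
  plateau detector returns the first index from which the forward running
  mean stays within a tolerance of the final mean (mean over the last
  quarter).
* **RDF**: histogram of inter-selection minimum-image distances, excluding
  intra-molecular pairs, normalized per frame by shell volume times the
  ideal-gas pair expectation at the instantaneous box volume.  Bin width
  defaults to 0.1 Å; r_max may not exceed half the smallest box edge.  Raw
  integer counts are retained so the histogram is auditable.
* **Hydrogen bonds**: a donor–acceptor pair is bonded in a frame when the
  donor-heavy to acceptor-heavy distance is ≤ 3.2 Å and the donor–H⋯acceptor
  angle is ≥ 158° for ANY hydrogen linked to the donor (the published
  criterion does not say "all"; "any" is the permissive reading).
  Occupancy is the fraction of analysed frames satisfying this; a class
  occupancy pools all pairs of a donor-class/acceptor-class combination.
* **Aggregates**: connected components of the molecular contact graph with
  a link when any inter-molecular heavy-atom distance is ≤ the cutoff
  (default 4.0 Å, a parameter — "aggregate" has no standard quantitative
  definition).  Partitions at a smaller cutoff provably refine those at a
  larger one.
* **Per-molecule energies**: at a fixed stride (default 100 ps, nearest
  frame at or after each tick) along the equilibrated window, each drug
  molecule in an aggregate of size ≥ 2 is scored against the rest of its
  aggregate (drug:drug), and — when an oligomer is present — against the
  rest of the drug–oligomer complex; the drug:oligomer energy is the
  difference of the two.  Isolated molecules are neglected.  Because each
  molecule is scored against the rest, every intra-aggregate pair energy
  appears in exactly two rows; rows are averaged, never summed.  Mean, SD
  and a seeded bootstrap (resampled means, 95% percentile interval) are
  reported.
* **Energy backend**: the decomposition takes any symmetric,
  pairwise-additive evaluator.  The shipped toy backend combines
  Lennard-Jones (Lorentz–Berthelot), Coulomb (332.0636·q_iq_j/(ε_r·r),
  constant or distance-dependent ε_r), and an optional Born-style screening
  term −(1−1/ε_w)·332.0636·q_iq_j/√(r²+a²e^{−r²/4a²}) reported as the
  solvation component; terms are cutoff at 12 Å with an energy shift, and
  distances below 0.1 Å are clamped with a warning.  It is a stand-in with
  the same call structure as a generalized-Born pipeline, not a solvation
  model; accordingly only the decomposition procedure and directional
  trends are asserted, never literal interaction-energy magnitudes.

## Toy dynamics generator (`assdkit.toysim`)

The generator emulates the *layout* of the reference supersaturated boxes
(11–13 drug molecules, optionally one oligomer chain and neutralizing Na⁺
counterions) at bead resolution, so the analysis operators and the
qualitative aggregation phenomenology can be exercised without external
data.

* A drug is 5 beads: core, donor heavy atom with one bonded polar
  hydrogen, acceptor, and a tail bead, held by harmonic bonds at the
  template geometry (k = 10 kcal/mol/Å², chosen inside the Euler stability
  bound 2k·dt/γ < 2).  The neutral charge set mimics a polar molecule
  (±0.3–0.45 e); the anionic set carries −1 total next to the acceptor with
  a strongly reduced donor dipole, since a deprotonated donor no longer
  donates.  Counterions are single +1 beads with a hydrated-ion effective
  size (σ = 6 Å) so they screen rather than bridge.
* The oligomer is a 20-bead harmonic chain with every third bead an
  acceptor; bead ε (`oligomer_eps_scale`) is the drug–oligomer attraction
  dial.
* Dynamics are overdamped Langevin: x ← x + FΔt/γ + √(2kTΔt/γ)·N(0,1),
  periodic wrapping, bitwise deterministic per seed.  Robustness measures:
  a noiseless pre-relaxation quench (200 steps) removes insertion overlaps;
  per-pair attractive forces are capped (repulsion is not, so cores never
  interpenetrate); the deterministic per-atom step is trust-region capped
  at 0.3 Å; any step larger than 2.5 Å aborts with a diagnostic, and
  parameter sets whose initial deterministic displacement exceeds 0.5 Å are
  rejected.  Implicit solvent (ε_r = 20 by default) keeps desk-scale cost.
* `plant_hbonds` overwrites donor/H/acceptor geometry in an exactly
  counted, seeded subset of frames (conforming: d = 2.9 Å, angle ≈ 175°;
  non-conforming: d = 4.5 Å), so occupancy recovery can be tested exactly.

**Study conditions.**  The directional studies run 13 drugs in a 34 Å box
(the supersaturated 112 Å all-atom box scaled to bead resolution and
desk-scale diffusion times), 20 000 steps of Δt = 0.02 at kT = 0.4 kcal/mol
and friction 0.25, with aggregate contact cutoff 5.5 Å (the Lennard-Jones
contact distance of 4 Å beads is ≈4.5 Å, so the all-atom 4.0 Å heavy-atom
cutoff is too tight for beads).  The neutral arm uses strong drug–drug
attraction (ε = 3.5 kcal/mol core wells), the anionic arm weak attraction
(ε = 0.2) plus monopole repulsion.  The oligomer-competition study runs 10
drugs (ε = 1.5) with one chain whose bead ε is scaled 0.3× (weak) vs 10×
(strong); at the strong setting the drug–oligomer cross-well exceeds the
drug–drug well, so the chain out-competes drug–drug contacts.  These
parameters were chosen once to place the paired arms on the two sides of
the transition each study is designed to exhibit — aggregation versus
dispersal, and oligomer-dominated versus drug-dominated contacts — and are
recorded in `pipeline.TOY_STUDY` and the study-function defaults.

**What passing does and does not show.**  The toy model reproduces the
*direction* of the reference observations (neutral drugs aggregate, anionic
drugs disperse; a more attractive oligomer weakens drug:drug energetics).
It has no water structure, no force-field realism, no crystallization, and
its energies are not comparable in magnitude to MM/GBSA values; passing the
directional tests says the analysis operators and the study design are
sound, not that the toy physics is predictive for real formulations.

## Pipeline (`assdkit.pipeline`)

`run_trajectory_study` chains generation → equilibration split → RDF +
hydrogen bonds + aggregates → energy decomposition + bootstrap, and writes
CSV/JSON plus a plain-text summary; any stage failure aborts with a
stage-named error and removes partial outputs.  Reports contain no
wall-clock data, so a rerun with the same configuration and seed is
byte-identical; the report structure is validated against a shipped JSON
schema generated from the report model.  `demo_end_to_end` runs a small
8-drug + oligomer configuration (~10 s) as the reproducible smoke test.

## Numerical notes and limitations

* Mass arithmetic uses 2021 standard atomic weights; formula/mass
  consistency is enforced at ±0.05 Da.
* Nearest-integer rounding everywhere an integer count is derived from a
  continuous quantity (ion pairs, planted frame counts).
* The miscibility verdict boundary (Δδ = 7) is declared immiscible.
* Fedors volume corrections may be negative per entry; only the summed
  molar volume must be positive.
* Triclinic cells, explicit solvent, real force fields and GB solvation are
  out of scope; the energy backend is pluggable precisely so a real
  evaluator can be substituted.
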