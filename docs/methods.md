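# Methods

## Scope

`tauramd` implements the analysis stack of the τRAMD (τ-random-acceleration
molecular dynamics) protocol for protein–protein complexes: residue-pair
contact matrices, five dissociation-time criteria, the bootstrap
residence-time estimator, interaction-fingerprint clustering of unbinding
routes, interfacial/buried water counting, and harmonization of
experimental kinetic constants. Because running the protocol on real
proteins requires a patched MD engine and microseconds of all-atom
simulation, the package also ships a coarse-grained two-body Langevin
simulator that reproduces the *protocol* — the random-force logic, the
replica scheme, the stop criteria — at desk scale, so every downstream
module can be exercised and validated end to end.

## The random-force protocol

A force of fixed magnitude and random orientation is applied to the
center of mass (COM) of one binding partner (the "ligand" partner,
conventionally the smaller protein) and distributed over its atoms by
mass-weighting, so the per-atom forces sum exactly to the COM force. The
ligand COM displacement is checked every 100 fs; if it fell short of
0.025 Å, a new direction is drawn uniformly on the sphere — the force
only reorients when it is not producing motion. A trajectory ends when
the partner–partner COM separation exceeds a stop distance (70 Å in the
all-atom convention) or is censored at the maximum duration (40 ns).
Campaigns consist of several replicas — independently equilibrated
starting configurations — each spawning a batch of trajectories
(recommended: ≥5 replicas × ≥15 trajectories, which
`validate_campaign` warns about but never enforces).

## Coarse-grained simulator

Two semi-rigid bead bodies are bound by native contacts and integrated
with overdamped Langevin dynamics in reduced units (k_BT = 1, lengths in
Å, times in ps):

    dx = (F/γ) dt + √(2 T dt/γ) N(0,1),   dt = 0.02 ps, γ = 1.

Energetics:

- **Intra-body springs** between every bead pair of a body (rest length =
  built distance, k = 25 kT/Å²) keep each body semi-rigid.
- **Native contacts** between chosen ligand/receptor bead pairs use a
  Morse well `D_e (1 − e^{−a(r−r0)})²` on the extension side; the
  compressed side (r < r0) is replaced by its harmonic expansion with the
  matched curvature 2 D_e a², because the exponential repulsive branch of
  the Morse potential produces forces that grow without bound under
  thermal compression and destabilize any fixed-timestep integrator.
- **Non-native cross-body pairs** feel a capped soft repulsion
  `ε (1 − r/r_c)²` (ε = 2 kT, r_c = 4 Å).
- The receptor is tethered harmonically to its built position
  (k = 5 kT/Å²); the ligand is free.

A "mutant" scales the well depth of chosen contacts (`ToyComplex.mutate`),
the coarse analogue of an alanine substitution at an interface residue.

Force magnitudes are quoted in the all-atom convention (kcal/mol/Å; the
protein–protein work used 17 and 19) and mapped linearly to reduced units
by `force_scale` (default 0.1 kT/Å per kcal/mol/Å).

**Default toy system and regime.** The reference complex has 5 receptor
and 3 ligand beads with four native contacts of depth 4.5 kT and Morse
range a = 0.4 Å⁻¹. These defaults were chosen so that escape is
*thermally activated* (the applied force alone cannot rip all contacts),
which is the regime where the protocol is informative: with a wide,
moderately deep well the work term F·x‡ of the applied force is large
enough that dissociation times respond measurably both to the force
magnitude (17 → 19 shortens the median by roughly a third) and to
halving one contact's well depth, while median escape stays near 0.1–0.3
ns so a full 5 × 15 campaign runs in minutes on one core. Deeper or
narrower wells make escape magnitude-insensitive (direction-waiting
dominates); much shallower ones make it drift-dominated.

**Scaled thresholds.** Two lengths are scaled from the all-atom
convention to the toy geometry, and both remain configurable: the stop
distance defaults to 4× the bound-state COM separation (the 70 Å all-atom
value is ~4 bound-state separations for a small complex), and in the
pipeline the contact threshold d_rr is set to 1.15× the longest native
rest length with the pair cutoff at 2.2× d_rr (mirroring how 5.5 Å / 15 Å
relate to atomic contact distances). The displacement-check threshold is
kept at the protocol's 0.025 Å; note that a diffusive toy ligand
almost always exceeds it, so redraws are rare while bound — the check
matters in the all-atom setting, where bound-state COM motion per 100 fs
is far smaller, and in the toy's strongly-pinned configurations.

**Reference point of the displacement check** is the ligand COM at the
previous check, which the protocol implies but does not state.

**Seeding.** All campaign randomness derives from a single base seed via
splitmix64 mixing of (base, replica, trajectory), so reruns are bitwise
identical across platforms.

## Contact analysis

Protein–protein residue pairs (PP-REs) are all cross-partner residue
pairs whose representative distance is within 15 Å *in the first frame*
of a trajectory; membership is not re-evaluated per frame, which keeps
matrix columns stable across frames (the cutoff is generous). The
representative distance of a pair in a frame is the minimum over
COM–COM distances of *chemically compatible* interaction-group pairs —
donor↔acceptor, cation↔anion, aromatic↔aromatic, aromatic↔cation,
hydrophobic↔hydrophobic — plus the sidechain-carbon COM pair (backbone
heavy atoms for glycine). A config switch (`all_group_pairs`) evaluates
every cross-group pair instead, for users who prefer the agnostic
reading. The built-in per-residue-type atom tables (ring atoms of
Phe/Tyr/Trp/His; Lys NZ and Arg NE/CZ/NH1/NH2 as cations, protonated-His
ring nitrogens included; Asp/Glu carboxylates as anions; standard N/O
donor/acceptor sets; aliphatic carbons as hydrophobic) can be overridden
per residue name, which is also how nonstandard residues (and the toy
beads) are covered.

Binding-site contacts (BS-REs) are the PP-REs whose representative
distance is below d_rr = 5.5 Å for *strictly more than half* of the
pooled equilibration frames.

Per-frame extras: ligand-partner COM displacement from frame 0 (ΔCOM),
inter-partner COM–COM distance, and RMSD computed by superposing the
receptor Cα atoms onto frame 0 and evaluating over all protein Cα atoms
(receptor-frame RMSD tracks ligand motion; fewer than three fit atoms
falls back to translation-only superposition).

## Dissociation criteria and the residence-time estimator

Five per-trajectory dissociation times: the standard protocol records the
time the COM separation first exceeds the stop distance (`com_com`,
engine-recorded in the simulator, frame-based for imported matrices);
`by_residue_first` / `by_residue_last` use the first frame whose mean
BS-RE distance exceeds d_rr / the last frame where it is below;
`many_contacts_last` / `few_contacts_first` use the last frame with
strictly more / first frame with strictly fewer formed contacts than 50%
of the BS-REs (a frame at exactly 50% qualifies for neither). Unmet
criteria censor the event at the trajectory end.

One ordering subtlety: "first above" and "last below" differ by exactly
one frame when the mean distance crosses d_rr once and stays up, so the
guaranteed invariant is `by_residue_first ≤ by_residue_last + one
snapshot interval` (equality of the stricter form holds only when the
series recrosses). Tests assert the provable form.

Per replica, the residence time is the 50% point of the empirical CDF of
event times — the linearly interpolated median (with 1-based order
statistics and h = 0.5(n−1): t_(⌊h⌋+1) + (h−⌊h⌋)(t_(⌊h⌋+2) −
t_(⌊h⌋+1))). Censored events enter at their cap value, and estimates
carry the censoring fraction so users can judge whether the force
magnitude was sufficient. Bootstrapping (default 50 000 rounds of 80%
subsamples drawn *without* replacement; with-replacement available)
yields τ_repl and SD_repl; their mean and sample SD over replicas give
τ_RAMD and SD_RAMD. A replica with SD_repl > 0.5 τ_repl advises more
trajectories; SD_RAMD > 0.5 τ_RAMD advises more replicas. A calibration
helper recommends the smallest force magnitude whose censored fraction
for the slowest system stays below 10%. The method yields *relative*
residence times; no absolute k_off calibration is attempted.

## Pathway clustering

Frames of each dissociating trajectory from 200 frames (2 ns at 10 ps)
before its `by_residue_first` event to trajectory termination are pooled;
censored trajectories are excluded. Fingerprints are binarized at d_rr
(columns never in contact are dropped — they cannot affect Jaccard
distances) and compared with the Jaccard distance (defined 0 for two
empty contact sets). K-means (10 restarts, fixed seed) clusters the rows
of the distance matrix — the literal published procedure; since
clustering distance-matrix rows as feature vectors is unconventional, a
`fingerprints` mode clusters the binary vectors directly. k defaults to
a fixed count (8 for protein-scale interfaces, 4 in the toy pipeline) or
`"auto"`, which scans 2–12 and takes the best mean silhouette, breaking
ties toward fewer clusters. Labels are renumbered by ascending
cluster-mean ΔCOM; a switch orders by COM–COM distance instead (the two
published descriptions differ; ΔCOM, the Methods definition, is the
default). The flow graph counts label transitions between consecutive
frames of the same trajectory: per ordered pair, frame-transition count,
distinct-trajectory count, and net flow.

Last-contact analysis selects pre-dissociation frames with at least one
but strictly fewer than three contacts, clusters them hierarchically
(average linkage on Jaccard distances, dendrogram cut at 0.5 — the
published account names neither, so both are documented defaults) and
reports each pattern group with its member pairs (those present in over
half the group's frames) and distinct-trajectory coverage.

## Waters

A water is interfacial when its oxygen is within 3.5 Å of at least one
heavy atom of *each* partner — the bridging reading of "within 3.5 Å of
both proteins", consistent with the water-bridge interpretation of
interface hydration; an `either` mode implements the disjunctive
reading. Buried waters are counted against a named anchor-atom
selection; the barnase–barstar anchor set (oxygens of barstar D35/D39,
OD2 of D54, backbone N/O of barnase L42/R83 and barstar D35/V45) ships
as the `bnbs` preset.

## Experimental kinetics

Literature series are stored long-form (mutant, series_id, quantity,
value, sd) with the wild type as reserved id "WT". Each series is
normalized by its WT value and rescaled by the reference series' WT
value; per-mutant values are the mean over series with their sample SD.
Derived quantities: K_d = k_off/k_on, and k_off = k_on·K_i when an
inhibition constant was measured (this is the dimensionally consistent
relation: K_i carries molar units), with relative errors combined in
quadrature. τ_exp = 1/k_off. Computed vs experimental residence times
are compared by OLS in log₁₀–log₁₀ space (the quantities span orders of
magnitude); R² is the squared Pearson correlation, and a linear-space
fit is available behind a flag.

## Synthetic fixtures and what passing tests show

The fixture generators plant truths that are computable without the code
under test: a comb geometry in which every planted pair distance is
dialed in exactly (each residue pair isolated by 100 Å so no cross talk
enters the 15 Å cutoff); event times from lognormal/exponential/constant
distributions with known medians; two-block fingerprint partitions; and
hand-placed water scenes. Estimator-recovery checks compare the *mean*
of cdf50 estimates over 30 replicated n = 200 fixtures against the true
median (5% lognormal, 7% exponential tolerance): a single n = 200 sample
median of an exponential has ~10% sampling error, so a one-draw check at
that tolerance would measure luck, not the estimator.

The toy model emulates stochastic first-passage dissociation under the
random-force protocol, force- and well-depth-dependent kinetics, and
progressive contact loss along unbinding routes. It does not emulate
conformational gating, solvent effects, rebinding after partial egress,
or the chemical specificity of real interfaces — so passing tests
validate the protocol logic, the estimators and the analysis algebra,
not the accuracy of any particular all-atom prediction.

## Problem sizes and numerical choices

Campaign-scale checks use 5 replicas × 15 trajectories per system (the
protocol's recommended minimum); distribution-level simulator checks use
50 trajectories per condition and 100 for the drift-limit closed form;
bootstrap checks use 5 000 rounds (the production default of 50 000 is a
CLI/knob choice — the estimate is insensitive beyond a few thousand).
Tolerances: drift-limit mean first-passage within 15% of
stop·γ/F (direction randomization and diffusion contribute small
corrections of order d₀/R); oracle comparisons are exact to 1e-10;
stochastic orderings use rank-sum tests at p < 0.01. Degenerate inputs:
constant bootstrap samples return SD 0; single-frame windows and
single-atom superpositions fall back to translation-only RMSD; empty
last-contact selections warn and return an empty report rather than
raising.

## Known limitations

- The toy simulator's unit mapping is arbitrary by construction; only
  orderings and ratios of its residence times are meaningful.
- PP-RE membership fixed at frame 0 can miss pairs that approach later
  in a trajectory (irrelevant for dissociation, which moves apart).
- The interaction-group tables cover the 20 standard residues and common
  His protonation variants; everything else requires an override.
- Binary MD formats are supported only through the adapter contract;
  multi-model PDB and the plain-text frame container are first-class.
- No Markov-state modelling, kinetic rates from cluster transitions, or
  free-energy surfaces are attempted, and no absolute residence times.
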