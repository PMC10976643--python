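# Methods

This note documents the models, parameters and design decisions behind
phos31: what each stage assumes, which knobs matter, what the synthetic
generator does and does not emulate, and where behaviour was a genuine
design choice rather than a forced consequence of the problem.

## Problem setting

³¹P chemical shifts of nucleotides (ATP, ADP, and the putative hydrolysis
intermediate ADP·P_i — ADP with a detached, singly protonated inorganic
phosphate HPO₄²⁻) are exquisitely sensitive to local geometry: a 0.10 Å
change in a single P–O bond moves the shift by ~10 ppm. An
ensemble-averaged prediction therefore couples three ingredients: the
conformational ensemble (MD snapshots), the electronic-structure model
that maps a snapshot to per-nucleus isotropic shieldings σ, and the
referencing scheme that converts σ to observable shifts δ. phos31
implements the full chain with the electronic-structure step behind a
pluggable engine contract.

## QM-region carving

**Union rule.** A residue or molecule is a QM member iff any of its atoms
lies within `cutoff_A` (default 3.8 Å, inclusive `≤`) of any core atom in
any frame. The core is the phosphate backbone (all mapped P and O labels)
plus the five-membered sugar ring (C1′–C4′, O4′); adenine base atoms are
excluded. Membership granularity is whole residues/molecules: one atom in
range pulls in the unit. The union over frames reflects solvent exchange
— many more waters visit the first shell over a trajectory than occupy it
in any single frame — and membership is fixed ("static") thereafter; only
link-atom positions are recomputed per snapshot. Proximity, not
biological role, decides membership: catalytically important residues
beyond the cutoff stay MM. Exact ties (a residue at exactly 3.8 Å) are
included.

Whether the sugar O4′ and the glycosidic atoms belong to the core is not
dictated by the problem; we include the whole five-membered ring and
document the choice. The core set is configurable (`core_labels`).

**Boundary cuts.** Only nonpolar C–C bonds are cut, to avoid spurious
polarization at the boundary:

* isolated member amino acid → one cut (C_β, C_α), side chain in QM;
* run of ≥ 2 consecutive member residues → C_α–C_carbonyl cuts at the
  run's termini. At the N-side the preceding residue's carbonyl group
  (C=O) joins QM so the peptide group stays intact; at the C-side the
  run's last carbonyl leaves QM.

Because the N-side cut pulls two atoms of a *non-member* residue into the
QM set, `QMRegionSpec` carries an explicit atom-level `qm_atom_indices`
alongside the residue-level member list; invariants about cuts are
enforced at atom level. A member amino acid that connects to the MM
region only through polar bonds (glycine, which has no C_β) cannot be cut
legally; the planner raises and demands the neighbour be added. A
spatially isolated member fragment with no crossing bonds needs no cut.

**Link atoms.** Each cut (q, m) is saturated by a hydrogen at
`pos(q) + L·unit(q→m)` with L = `link_bond_length_A` (default 1.09 Å),
one per cut per snapshot; link atoms carry zero formal charge.

**Charges.** The QM total charge of a snapshot is the integer sum of the
member units' formal charges from a residue-keyed charge table (ATP −4,
ADP −3, PO4/HPO4 −2, Mg +2, arginine/lysine +1, aspartate/glutamate −1,
water 0, …). Charges attach to chemical identity, not to atoms, which is
why the table is external, two-column text. Charges are computed per
snapshot; with static membership they are constant across frames, and the
pipeline verifies this rather than assuming it.

**Size convergence.** `converge_qm_size` scans strictly increasing cutoff
radii, recomputes the union region and the per-nucleus ensemble-mean
shieldings at each, and reports the smallest radius whose means change by
at most `tol_ppm` relative to every *larger tested* radius. The largest
radius has no larger evidence and cannot be certified; if no smaller
radius qualifies, the report flags non-convergence, and a single-radius
scan is flagged as not assessable.

## Shielding surrogate

The shipped engine is a deterministic geometric model:

σ(P) = σ₀ + a·Σ_O (d(P–O) − d_ref(class O)) + b·(⟨∠O–P–O⟩ − θ_tet) + c·Σ_j q_j/r_j

| parameter | default | unit | rationale |
|---|---|---|---|
| σ₀ (`sigma_base`) | 300 | ppm | typical ³¹P absolute shielding scale |
| a (`bond_slope`) | −100 | ppm/Å | anchored: +0.10 Å on one bond ⇒ −10 ppm in σ, i.e. 10 ppm downfield in δ |
| d_ref terminal / bridging | 1.50 / 1.60 | Å | terminal P–O bonds (charged or double-bond O) are ~0.1 Å shorter than phosphoanhydride/ester bonds |
| b (`angle_slope`) | 0.05 | ppm/deg | plausibility choice; small relative to the bond term |
| θ_tet (`reference_angle_deg`) | arccos(−1/3) ≈ 109.47° | deg | exact tetrahedral angle, so an ideal tetrahedron contributes zero |
| c (`charge_slope`) | 2.0 | ppm·Å/e | plausibility choice for electrostatic polarization |
| ion horizon (`ion_cutoff_A`) | 6.0 | Å | QM-member single-atom ions beyond this contribute nothing |

Only the bond slope is anchored to the empirical structure–shift
coupling; the other coefficients are configuration, not constants. Oxygen
class is decided from topology: an oxygen bonded to ≥ 2 phosphorus/carbon
atoms is bridging, otherwise terminal (metal coordination does not
count). The surrogate depends only on internal coordinates and relative
ion distances, hence is exactly invariant under global rotation and
translation. Each P must have exactly four oxygen neighbours; the broken
bridge of ADP·P_i (P_i, P_β) is the documented exemption. External DFT
engines plug in as callables with the same per-snapshot signature; none
is shipped.

## Referencing

δ_i = σ_ref − σ_i + δ_exp(P_α), with σ_ref the ensemble mean of σ(P_α)
over a designated reference ensemble. P_α is the internal reference
because it is not involved in hydrolysis and its chemical environment
changes little between states. By construction the reference ensemble's
mean δ(P_α) equals the supplied experimental value exactly, systematic
engine offsets cancel, and δ_i − δ_j = σ_j − σ_i independent of the
reference. The exact arithmetic behind published internal-referencing
variants differs between groups; this formula is our documented choice,
and the reference state is configuration. Experimental shifts are user
data; the defaults in `pipeline.DEFAULT_EXPERIMENTAL_SHIFTS` are
representative values for the three states, not computed quantities.

## Ensemble statistics

* Spread = max − min; mean arithmetic.
* Rolling averages default to a trailing (causal) window of 20 snapshots
  with prefix shortening; whether published rolling curves are trailing
  or centered is typically unstated, so centering is config
  (`trailing | centered`).
* Deviation tables print |δ̄_calc − δ_exp| per nucleus, rounded half away
  from zero to two decimals; the row average P̄ is computed from the
  *unrounded* deviations and rounded last. Rounding half away from zero
  matches printed-table convention (IEEE round-half-even would print
  0.925 as 0.92).
* Peak order sorts nuclei by mean δ, most downfield first; exact ties
  fall back to canonical order (P_α, P_β, P_γ, P_i) with a tie flag.
* Boxplot summaries use linear-interpolation quartiles (conventions
  differ; this one is documented), whiskers clipped to the most extreme
  datum within 1.5×IQR, outliers beyond.

## Classification

`select_extreme_populations` takes the n most downfield and n most
upfield frames of the δ(P_β) series (default n = 150). Ties break by
frame index, earlier wins; the downfield set is selected first and the
upfield set from the remainder, so a fully degenerate series splits the
first 2n frames by index, flagged.

The feature list describing the P_β environment has 24 named entries for
ADP·P_i and ATP: the backbone-fold angle φ(P_i–P_β–P_α) (φ(P_γ–P_β–P_α)
in ATP), all P–O bonds of the backbone, the detachment distance
d(P_i–O_3B), P–P separations, the six O–P_β–O angles, bridge angles and
backbone dihedrals. Which 24 features best span the P_β environment is
not canonical; the list is configuration (`FeatureSpec`), and 24 is the
declared count, padded with backbone internal coordinates. ADP, lacking
a third phosphorus, has a 17-entry default.

Importance = |coefficient| of an L2-regularised logistic regression
(C = 1, lbfgs) on features standardized to zero mean/unit variance —
hence invariant to affine rescaling of any input feature. Error bars are
the SD of coefficients over 200 bootstrap resamples of the rows;
held-out accuracy is stratified k-fold (k = 5, clamped to the class
size). Zero-variance features are dropped with a warning — the generator
legitimately produces some (its tetrahedra are exact, so some angles are
constant). Near-duplicate features (|r| ≥ 0.95) are reported because
correlated features share importance. The estimator, regularisation and
error-bar procedure are our documented defaults, all configurable; all
stochastic steps take an explicit seed.

## Synthetic-data generator

The generator's job is *controllable statistics*, not physics. Geometry
is built from internal coordinates: exact tetrahedral phosphate groups
(terminal completion in closed form), the chain assembled by NeRF-style
placement, and the fold angle φ — the angle at P_β subtended by P_α and
the third phosphorus (P_γ or P_i) — solved to its target by bracketing +
Brent root finding on a placement dihedral. Templates embed the study
conditions exactly: terminal 1.50 Å / bridging 1.60 Å (class offset
0.10 Å), d(P_i–O_3B) = 3.42 Å with a bridging Mg²⁺, elongated φ = 130°,
folded φ = 90°.

Frame perturbations are independent Gaussian draws on the P–O bond
lengths (rebuilt to Cartesians each frame), the fold angle (SD 3°) and
the detachment distance (SD 0.05 Å). Regimes: QM_like draws bonds at the
reference means with SD = `bond_noise_sd` (default 0.01 Å); MM_like
shifts all means by −0.07 Å — except the most refinement-sensitive
bridge bond (P_β–O_3A; additionally P_γ–O_3B in ATP) at −0.15 Å — and
doubles the SD. This encodes the force-field pathology the analysis
contrasts: bonds systematically short and broad before refinement, long
and narrow after, with a +0.15 Å refinement signature on P_β–O_3A. The
"geometry optimization" stage of the pipeline is therefore represented
as regime selection, not a minimizer: contrasting MM-like input with
QM-like input reproduces the analysis pattern without an electronic-
structure optimizer.

Environments: rigid 3-site waters and single-atom ions placed by
rejection sampling in distance bands around the core. Guaranteed members
sit in the 2.9–3.5 Å shell; most member waters are *exchange* waters
based outside the cutoff that visit the first shell in one randomly
assigned frame — this is what makes union membership much larger than
any single frame's shell, as in real solvent exchange. Guaranteed
non-members stay ≥ 5 Å (so even their hydrogens cannot cross 3.8 Å under
the per-frame jitter of SD 0.03 Å, clipped at 3σ). Water counts are
tuned so the carved region holds 200–250 atoms in solution and 500–700
in the pocket. The pocket mimic places 16 member residues on two chains
(two-protomer convention) as tripeptide stubs — side chain pointing into
the pocket, glycine neighbours bonded through real peptide C–N bonds but
kept outside the cutoff — so boundary-cut planning is exercised with 16
C_β–C_α cuts. Side chains are extended linear stubs, not
rotamer-correct.

The ensemble topology is the generator's covalent bond list:
distance-inferred bonds restricted to intra-residue bonds plus peptide
C–N bonds (`structures.covalent_topology`). Plain distance inference
would misread metal coordination and close H···H contacts as covalent
bonds; the CLI applies the same rule when a trajectory arrives without
explicit topology.

A planted effect `(feature, gap)` shifts the named builder parameter (the
fold angle, the detachment distance, or any P–O bond) by `gap` in the
frames *destined to be downfield* under the surrogate — the half of the
frames whose summed P_β–O bond draws are longest, hence lowest σ(P_β).
Selecting extreme populations later recovers essentially this class
structure, so planted-feature recovery tests the full chain. Planting a
feature absent from the state's default `FeatureSpec` is an error; other
feature kinds (O–P–O angles, dihedrals) are structurally fixed by the
exact-tetrahedron construction and cannot be planted.

All randomness flows from one seed; each frame draws from its own
counter-based stream (`default_rng([seed, tag, frame])`), so frame k is
reproducible in isolation and generation is byte-identical across runs.

**What passing tests show about real data — and what they do not.** The
generator reproduces the *statistical shape* of the analysis inputs
(bond-length regimes, conformer populations, region sizes, planted
class structure) but none of the physics: no force field, no solvent
dynamics, no electronic structure, no anisotropy, no exchange kinetics.
Green tests certify the bookkeeping, geometry and statistics of the
pipeline, not the accuracy of any shielding prediction on real
trajectories — that depends on the plugged-in engine and sampling.

## Numerical choices

* Distance tests are inclusive; the union query uses a KD-tree with a
  1e-12 tolerance pad at the cutoff.
* Bond inference: (i, j) bonded iff d ≤ R_i + R_j + tolerance (default
  0.4 Å), Cordero covalent radii.
* Link-atom direction requires |q − m| > 1e-8 Å (coincident atoms raise).
* Dihedrals are IUPAC right-handed in (−180°, 180°]; collinear triples
  raise. Dihedrals at ±180° are the same torsion (tests compare
  circularly).
* Fold-angle solving brackets on a 5° grid and refines with Brent to
  1e-10; targets outside the attainable cone fall back to closest
  approach (the manifest records the targets).
* Snapshot extraction picks, for each multiple of the interval from t=0,
  the earliest frame at or after it (1e-9 ns tolerance); idempotent at a
  fixed interval.
* Frame indexing is 0-based; the time origin is the first frame.
  Coordinates are Å throughout; inputs are assumed unwrapped — wrapped
  (periodic-image) trajectories are unsupported.

## Problem sizes

Default test and acceptance runs use the sizes the analyses need, kept
modest by construction: 10–60 frames for unit fixtures, 300–400 frames
for regime statistics (SE of a bond-mean difference ≈ 0.001 Å at
n = 300, far below the 0.01 Å assertion window), 120 frames for the
spread contrast, 20 seeded 150+150 splits for recovery, and one full
900-frame pocket run end-to-end.

## Known limitations

* The surrogate's angle and charge terms are plausibility-scaled; only
  the bond term is anchored. Do not interpret surrogate σ values as
  physical shieldings.
* Residue-level membership granularity means a large member unit (e.g. a
  lipid) would enter whole; only amino-acid backbones are trimmed.
* No charge redistribution or smearing at the QM/MM boundary; MM point
  charges are the unit formal charge spread uniformly over the unit's
  atoms in the exporter.
* Multi-model PDB and multi-frame XYZ only; binary trajectory formats
  (DCD/XTC) would be adapters, not core.
* The PDB writer (biotite) limits residue names to 3 characters, so the
  inorganic phosphate residue is `PO4`; the charge table also accepts
  `HPO4` as a key.
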