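# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `opsindiff`.  Everything stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is quoted from external
runs.

## Data model and I/O

Structures and trajectories are plain-text PDB: a topology PDB plus a
multi-model PDB (MODEL/ENDMDL) trajectory.  This dialect was chosen as the
mandatory format because it is inspectable to the last coordinate and
round-trips exactly at the stored 10⁻³ Å precision; binary formats (DCD,
XTC) can be converted externally.  Author residue numbering is
authoritative throughout — tuning sites are always referred to by author
numbers (113, 122, 181, 296-style) — and internal atom indices are 0-based.
The reader reports malformed fixed-width records with their line number and
per-MODEL atom-count mismatches with the model number; the writer's output
is cross-checked in the tests against an independent PDB parser (biotite).

Sequence identity uses Biopython's global aligner with BLOSUM62, gap open
10, gap extend 0.5; identity = matches / alignment length × 100.  These
parameters are a documented convention: for equal-length close homologs the
result is insensitive to them.

## Geometry

* **Superposition** — weighted Kabsch via SVD with the determinant
  correction (proper rotations only).  Degenerate (< 3 points or collinear)
  inputs error.  Verified against `scipy.spatial.transform.Rotation
  .align_vectors` to 10⁻⁶ on randomized cases.
* **RMSD/RMSF** — unweighted (Cα convention); RMSF aligns all frames to
  frame 0 on the alignment selection before computing
  √⟨|xᵢ(t) − ⟨xᵢ⟩|²⟩.
* **Rg and centre-of-mass distances** — mass-weighted by default.
* **Dihedrals** — IUPAC sign convention on (−180°, 180°], matching the sign
  returned by the standard MD analysis libraries (MDAnalysis, biotite,
  mdtraj), verified against an independent closed-form oracle and against
  biotite.  Angles are interior angles on [0°, 180°].  Degrees everywhere
  in the public interface.
* **Helix bend** — the ordered Cα list is split in half; each half is
  smoothed with a 4-residue moving average before the principal-axis line
  fit, and the angle between the two axes is returned.  The smoothing step
  exists because a raw line fit to half a helix is biased by several
  degrees (up to tens of degrees for ≲6-residue halves) whenever the half
  covers a non-integer number of helical turns; averaging over one turn
  (3.6 residues ≈ 4) collapses the helical radius onto the axis.  The
  metric remains a global two-axis angle, not a local kink detector, and is
  only trustworthy for helices of ≳14 residues.

## Pocket analysis

Pocket lining residues: a protein residue qualifies when any of its heavy
atoms lies within the cutoff (default 4.5 Å) of any chromophore heavy atom;
waters and hetero residues are excluded, and the covalently linked lysine
(identified by a ≤ 1.8 Å contact) can be excluded by flag (default:
included, since the classic 27-residue convention does not state its
treatment).

Pocket volume is a POVME-style grid count: a cubic grid (default 0.5 Å)
over the union of spheres (default 8 Å) centred on chromophore heavy atoms;
points within Bondi radius + probe margin (default 0) of any protein heavy
atom are deleted; volume = points × spacing³.  There is no
solvent-contiguity filter, so absolute volumes depend on the inclusion
radius; only relative (between-system, over-time) behaviour is
interpretable, and only such behaviour is asserted anywhere.  The estimator
converges to the analytic sphere volume with no blockers (verified to 2%)
and subtracts a single blocker's sphere to 5%; a Monte-Carlo rejection
oracle checks a random configuration to 2%.

Hydration: count of water oxygens within 4.0 Å (a near-hydrogen-bonding
range; the convention is exposed as a parameter) of any chromophore heavy
atom, per frame.

## Chromophore metrics

The chromophore is addressed through logical atom names mapped by a
`ChromophoreSpec` (N⁺, CA, CD, CE, C1…C16, C20); qualified aliases
(`LYS296:NZ`, `RET:C5`) support composite retinal + linked-lysine
topologies.  The β-ionone ring is C1–C6 and the polyene chain C7–C15;
"ring" and "polyene" targets are unweighted centroids of those sets, and
side-chain centroids exclude backbone N/CA/C/O — the field names these
regions without fixing atom sets, so these definitions are package
conventions.  Site-181-type distances use the carboxylate group
(CD/OE1/OE2 or CG/OD1/OD2) when present, falling back to the side-chain
centroid otherwise.

Torsion distributions are summarised as 36-bin (10°) circular histograms.
Modality is classified on a von Mises kernel density (κ = 50, ≈ 8°
bandwidth) evaluated on a 1° grid: local maxima above 10% of the global
maximum and pairwise separated by ≥ 30° are peaks; one peak → monomodal,
two → bimodal, more → top two with a multimodal flag.  Peak "heights" are
the fractions of samples circularly nearest each peak.  The classifier
requires ≥ 100 samples and is stable across seeds for well-separated
mixtures (≥ 95/100 seeded runs in the acceptance checks).

## Differential distance screen

Qualifying sites are residues whose Cα lies within 8 Å of any chromophore
heavy atom in frame 0 of either system (union) — frame 0 is a deterministic
and symmetric choice.  For each qualifying site and target (N⁺ atom,
β-ionone ring centroid) the screen compares per-frame Cα→target distances
between systems.  Because frames are autocorrelated, each series is reduced
to 10 contiguous block means and a Welch two-sample t-test runs on the
blocks; p-values are Benjamini–Hochberg corrected across all site/target
records; a record is labelled *closer*/*farther* only when q < α (0.05) and
|Δ| ≥ 0.5 Å.  Both the signed Å difference and the fraction of the
system-A mean are reported; the Å difference drives classification.  The
screen is exactly antisymmetric under exchanging the systems, and on null
(exchangeable) system pairs the labelled fraction stays below α + 0.03.

## Hydrogen bonds

Donors are N/O/S heavy atoms with at least one hydrogen within 1.3 Å in the
same residue (multi-model PDB carries no CONECT records for protein
hydrogens, so covalent D–H bonds are inferred by distance); acceptors are
O always and N only without attached hydrogens, with a per-(residue, atom)
override table; water oxygens are both.  A bond is present in a frame when
d(D,A) ≤ 3.5 Å and ∠D–H···A ≥ 150° for some H on the donor — the most
common MD convention; both thresholds are exposed.  Occupancy is the
fraction of frames; detection is verified frame-by-frame against a
brute-force all-pairs oracle.  A water bridge holds in a frame when one
water is bonded (either polarity) to both sites simultaneously.
Unprotonated structures are rejected with an explicit error rather than
silently returning nothing.

## Synthetic two-system generator

The generator emulates the statistical structure of a comparative pigment
MD experiment, not its physics: 20 minimal polar residues (N,H,CA,C,O plus
an inward-pointing OG/HG hydroxyl) on a 12 Å sphere around a retinal-like
chromophore carrying every logical atom, plus 6 shell waters.  Study
conditions of the default configuration (all exposed in
`ToySystemConfig`):

* radial displacements of **+1.0 Å** at two cage sites in system B —
  chosen as sites that robustly satisfy the screen's 8 Å qualifying cutoff
  under every seed;
* hydrogen-bond occupancy tiers **0.99 / 0.80 / 0.18** and a
  **0.5**-occupancy water bridge, mirroring the high/medium/low occupancy
  tiers reported for counterion-type interactions in comparative opsin
  studies;
* von Mises torsion plans: Schiff-base twist 170° (κ=20) vs 150° in system
  B; ring–chain torsion C7-C6-C1-C16 monomodal (+65°, κ=8) in A vs an
  equal ±65° mixture in B; C5-C6-C7-C8 monomodal (−60°, κ=30) in both;
* a sinusoidal cage-breathing mode (amplitude 0.4 Å, period 50 frames),
  Gaussian positional noise σ = 0.1 Å, 2000 frames, one seed.

Noise σ and the programmed shift sizes follow the recovery conditions the
screen is specified to meet (1.0 Å shifts over 2000 frames with σ ≈ 0.1).
All randomness flows from the single seed through named sub-streams, so
adding waters does not perturb torsion draws; output is bit-reproducible
and stored at 10⁻³ Å.

Construction order matters and is deliberate: breathing and displacements
are applied to the noise-free base; torsion draws are imposed on the
noise-free chromophore (rotating a long moiety about a noise-perturbed
bond axis would amplify distal positional noise far beyond σ); Gaussian
noise is added; planned H-bond geometries (bonded: d = 2.8 Å, θ = 165°;
broken: d = 4.5 Å) are imposed exactly last, so recovered occupancies are
exact Bernoulli draws.  The chromophore template is posed in its resting
conformation (the modal torsion values) and centred on the midpoint
between N⁺ and the ring centroid, which keeps the two screen targets
symmetric about the cage centre and the radial-displacement → distance
mapping within a few percent of unity.  The per-system plan overrides
(`torsion_plan_b`, `hb_plan_b`) exist so that a single config describes a
matched contrast, e.g. monomodal-vs-bimodal.

What the generator does **not** emulate: force-field energetics, membrane
and lipid contacts, realistic amino-acid chemistry, solvent dynamics, and
autocorrelation beyond the breathing mode.  Passing recovery tests
therefore demonstrates the estimators' correctness and calibration on
known ground truth — not that any particular biological conclusion about a
real pigment pair is reproduced.

## Numerical choices and degenerate inputs

Zero-variance series in the block test return p = 1 when the means agree
(and 0 otherwise) instead of NaN.  Dihedrals map −180° → +180°; circular
statistics are invariant to adding 360°.  Selections may be empty (callers
decide); empty chromophore or protein selections error or warn as
documented per operation.  Volume grids are anchored to the chromophore
bounding box, making the estimate rigid-motion invariant to grid tolerance
(≈ 1%).  The acceptance script keeps all problem sizes at the study
defaults (2000-frame pairs, 50 null runs, 100 modality runs, 400-frame
volume series), which completes in about half a minute on one CPU.

## Known limitations

* The helix-bend estimator is a global two-axis angle; it under-resolves
  local kinks and is unreliable below ~14 residues.
* Absolute pocket volumes carry no solvent-contiguity filter and are not
  comparable across different inclusion radii.
* The H-bond detector is purely geometric (no energetic scoring, no
  π-cation or salt-bridge classes).
* `pairwise_identity` counts gap columns in the denominator; tools that
  exclude end gaps may report slightly higher identity for distant pairs.
* The screen's false-positive control is calibrated for the generator's
  noise model (white noise plus a slow breathing mode); heavier
  autocorrelation in real trajectories may require more/longer blocks,
  which `ScreenParams.n_blocks` exposes.
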