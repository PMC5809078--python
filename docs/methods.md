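# Methods

## The observable

A protein-induced DNA kink is a sharp local deformation concentrated at
one base-pair step, geometrically an opening of the step toward one
groove and hence a large roll angle. We analyze individual roll angles
rather than a global bend so that sharp kinks are distinguished from
gradual curvature spread over several steps. A step counts as kinked
when its roll exceeds a threshold of **35°** (the screening default,
exposed as a parameter), and the *kink angle* of a complex is the
largest roll found in it.

## Base frames and step parameters

Every standard deoxynucleotide (A, C, G, T) carries an embedded
idealized geometry in the standard nucleic-acid reference frame: the
base in the xy-plane, x toward the major groove, y toward the strand-I
backbone. The observed base frame is the proper rigid transform
(Kabsch superposition, SVD with determinant correction) that carries
this standard geometry onto the observed ring + Watson–Crick
donor/acceptor atoms + C1′; at least 6 ring atoms must be present, and
the fit RMSD is reported. The base-pair frame averages the two base
frames after flipping the strand-II frame 180° about its x-axis; the
averaging halves the relative rotation vector (scipy `Rotation`), and a
relative rotation above 90° is rejected as non-Watson-Crick geometry.

Step parameters follow the mid-step-frame (CEHS-style) construction:

1. Γ = angle between the pair z-axes, computed as
   `atan2(|z_i × z_j|, z_i · z_j)` (the atan2 form keeps near-zero
   bending accurate to ~1e-13; an acos form loses six digits there);
2. both triads are rotated by ∓Γ/2 about the hinge `z_i × z_j`;
3. twist = signed in-plane angle between the rotated x-axes; the mid
   frame is the half-twist interpolation, its origin the midpoint;
4. φ = signed angle from the mid-frame y-axis to the hinge;
   roll = Γ·cos φ, tilt = Γ·sin φ;
5. (shift, slide, rise) = origin displacement in mid-frame coordinates.

Positive roll opens the step toward the minor groove. The construction
is closed under inversion: `apply_step` rebuilds the next pair frame as
`R_j = R_i · Rz(Ω/2+φ) · Ry(Γ) · Rz(Ω/2−φ)` with the origin advanced in
the mid frame, and measure∘build is the identity to machine precision —
the package's central oracle. Intra-pair parameters are zero in all
generated duplexes; only step-level roll is analyzed.

This is deliberately *not* a curvilinear-axis scheme: it is fully
specified, widely validated and exactly invertible. Comparisons against
values derived with curvilinear-axis software carry a ±3° convention
tolerance.

## Pair detection and curation

Watson–Crick pairs are called geometrically: complementary identities
(A:T, G:C only — wobble and Hoogsteen pairs are out of scope), C1′–C1′
distance in **8.0–12.5 Å**, at least **2** canonical donor–acceptor
contacts within **3.6 Å** (A:N1·T:N3, A:N6·T:O4; G:O6·C:N4, G:N1·C:N3,
G:N2·C:O2), and base planes inclined by at most **65°**. The window is
wide enough to keep steps kinked up to ~55° while rejecting stacked
non-pairs. Each base joins at most one pair, assigned greedily by
descending contact count with ties broken by the smaller C1′–C1′
distance. Pairs are then grouped into maximal antiparallel runs
(chain-adjacent on strand I, reverse-adjacent on strand II); every run
of ≥2 pairs is one duplex, and a model may contain several.

Curation mirrors what a manual screen does before trusting roll values:

- **Dangling ends.** Unpaired terminal nucleotides flanking the paired
  core are counted and excluded from step indexing, so step 1 always
  refers to the first true pair; overhangs cannot shift the register.
  The model-wide paired set is used, so bases belonging to a
  neighboring duplex segment are never mistaken for overhangs.
- **Flip-outs.** An unpaired base whose register partner exists but
  makes no canonical contacts is flagged as flipped out; a base with no
  partner residue at all is a dangling end. A 4.0 Å centroid-to-axis
  criterion (local axis interpolated between fitted pair origins)
  additionally catches bases displaced off the helix. Note a pure
  glycosidic rotation barely changes the centroid-to-axis distance
  (the rotation axis is nearly radial), which is why the contact
  criterion, not the distance, is the primary detector. Kinks at steps
  adjacent to a flagged position are annotated `flip_adjacent` rather
  than silently reported.
- Steps whose flanking frames cannot be fit (missing ring atoms) are
  reported missing instead of aborting the profile.

## Intercalation calls

At a kinked step, every amino-acid residue's sidechain heavy atoms
(CB and beyond; CA is backbone, so glycine can never intercalate) are
tested against the step slab: between the two base-pair mean planes
(signed distances of opposite sign, each ≤ **4.5 Å**) and within
**7 Å** of the mid-step origin. Residues with ≥1 inserted atom are
reported with their insertion depth — how far the deepest atom reaches
past the C1′–C1′ line (mean mid-frame x of the step's four C1′ atoms)
toward the helix axis. Classification is **full** when ≥50% of the
sidechain heavy atoms are inside the slab *and* the depth is ≥1.5 Å;
otherwise **partial**. The 50%/1.5 Å rule is a quantitative surrogate
for a visual full/partial judgement; both numbers are module constants
and borderline residues may classify differently than by eye.

## Trajectory statistics

Multi-model ensembles (multi-model PDB/mmCIF, or generator output) are
sampled at n equidistant snapshots, indices `floor(k·M/n)`, n = 2000 by
default. The roll matrix (snapshots × steps) yields per-step means
(missing steps excluded per column with counts), roll time courses, and
per-step histograms fit by nonlinear least squares to
`a·exp(b(x−c)²)` with b constrained negative, initialized from sample
moments, on fixed 2° bins spanning [−20°, 80°] (extended when data
exceed it). Degenerate (near-constant) samples are refused.

Kink-site stability is classified from the argmax-roll step within ±1
of the reference step, per snapshot:

- **unstable** when a neighboring step carries the maximum in ≥30% of
  snapshots (the kink shifts);
- otherwise **stable_large_kink** when the reference step's mean roll
  is ≥35°, else **stable_reduced_kink**.

The 30% occupancy cut and the 35° mean cut are surrogates for a
qualitative three-group distinction; both are parameters of
`classify_stability`.

## The synthetic generator

`build_duplex` chains `apply_step` from an identity pair frame and
places ideal base pairs (standard geometries, zero intra-pair
parameters) into each frame; atoms are ring + WC donor/acceptor
exocyclics + C1′, with no phosphate backbone — nothing downstream needs
one. `simulate_roll_ensemble` draws each step's roll independently per
snapshot from a normal distribution about the mean profile (default SD
8°, matching the near-Gaussian single-step roll histograms such
ensembles show), all other parameters fixed, fully reproducible from a
seed. `plant_intercalator` places near-planar sidechain templates
(VAL 3, LEU 4, MET 4, PHE 7 heavy atoms) with the deepest atom a chosen
depth past the C1′–C1′ line, backbone outside the slab, and rejects any
placement that brings an atom within 1.5 Å of a DNA atom.
`add_overhang` and `flip_base` plant the two curation cases.

Study conditions used throughout tests and the acceptance script: an
11-bp duplex (GCGTATACGCG) with a single 54° kink at step 5 — a sharp,
Sac7d-scale kink at desk scale — SD 8°, 2000 snapshots; planted wedges
at kink rolls 40–50° and depths 1.7–2.5 Å. Deeper plants at a ~50° step
would cross into the converging major-groove side of the slab and trip
the clash contract, which is physically sensible: the open wedge is on
the minor-groove side.

What the generator does *not* emulate: backbone and sugar atoms,
intra-pair deformations (buckle/propeller/opening), sequence-dependent
stiffness, correlated fluctuations between steps or in the other five
parameters, solvent and protein dynamics. Passing tests therefore show
that the measurement, curation and detection machinery is exact and
self-consistent on idealized coordinates — not that real crystal
structures are free of the disorder, modified bases and borderline
geometry a production screen must still be robust to (the error-row and
exclusion paths handle those).

## Numerical choices

- Angle extraction avoids `acos` near 0/π everywhere (atan2 of
  cross/dot; rotation vectors for frame averaging).
- Proper rotations are enforced in superposition (det = +1), so
  mirror-image coordinates cannot produce a left-handed frame.
- Highest-occupancy altloc wins (ties: first in file); hydrogens are
  ignored on read.
- Exclusion reasons are evaluated in a fixed order (RNA → modified →
  no duplex → non-crystal header) and only the first is reported; files
  without method metadata are accepted with a warning.
- Equidistant snapshot selection always includes the first model and is
  deterministic; requests beyond the model count clamp with a warning.

## Problem sizes

Round-trip and symmetry checks run 100–500 random profiles of 6–12 bp;
trajectory checks use one 11-bp duplex × 2000 snapshots; planted-wedge
sweeps use 100 fixtures of 12 bp. At these sizes the full test suite
and the acceptance script each complete in well under a minute of
wall-clock per major stage on a single CPU.

## Known limitations

- Exact numeric agreement with curvilinear-axis analyses of the same
  coordinates is bounded (±3° on kinked steps), not guaranteed.
- Insertion depth is defined for minor-groove approach; major-groove
  intercalators would need a mirrored reference line.
- The greedy pair assignment follows the stated tie-break (smaller
  C1′–C1′); under simultaneous extreme shift/slide distortions a
  cross-step contact can win a tie, which is outside the supported
  parameter domain.
- Sidechain *construction* (building back a longer residue from a
  shorter one) is out of scope; truncation only removes atoms and never
  moves the ones it keeps.
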