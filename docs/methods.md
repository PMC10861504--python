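# Methods

## The measurement model

`b1state` treats a receptor–G-protein complex as a hierarchy of chains,
residues and heavy atoms (hydrogens and waters are discarded on read;
deposited cryo-EM models carry no hydrogens and every criterion below is
heavy-atom based).  All quantities are defined on author residue
numbers, reached through class-B generic positions.

**Generic numbering.**  Within a transmembrane segment (or H8) the map
from a Wootten index `x.yyb` to the deposited author number is exactly
linear: one residue per 0.01 index unit.  A single anchor pair per
(receptor, segment) therefore fixes the whole segment; the shipped
anchors derive from residue↔position pairs attested in the structural
literature on GLP-1R, GCGR and GIPR.  `validate_table` re-checks every
attested pair against the linear model and reports inconsistencies
without resolving them — for GCGR two in-text pairs (P353 at 6.47b,
V358 at 6.59b) conflict with the receptor's own 6.33b anchor and with
the corresponding figure-legend value (V368); the tables follow
linearity (6.47b→356, 6.59b→368) and the raw pairs stay in the data
file, flagged.  The TM7–H8 junction asparagine carries the alias
7.61b ≡ 8.47b (both labels resolve to the same residue).  The GCGR H8
anchor is not attested directly; it is derived through that alias from
the attested Y400(7.57b), a derivation that exactly reproduces the
attested GLP-1R E408(8.49b) and GIPR E402(8.53b) when applied to those
receptors, which is the consistency argument for trusting it.  Segment
boundary ranges (used for "TMD Cα" scopes) are set per receptor to
cover every attested helix position without overlapping the loop
annotations; exact helix termini are not published, so boundary choices
are deliberately generous and are recorded in the numbering data file.

**Superposition.**  `kabsch` is the standard SVD solution of the
least-squares rigid fit with the reflection branch corrected
(det R = +1); near-collinear point sets are rejected rather than
silently fit.  Model-level superposition matches Cα atoms by generic
position (cross-receptor) or author number (same receptor) over a named
scope; the default scope is all matched TM-segment Cα atoms ("TMD Cα"),
and the matched residue list is stored in every result because the
choice of scope is the dominant uncertainty when comparing printed
displacement values (superposition scopes are rarely stated alongside
such numbers; ±1.5 Å / ±3° acceptance tolerances absorb this).  No
outlier trimming is performed: a single well-defined number beats an
iteratively edited one for reproducibility.

**TM6 kink.**  The kink is the literal planar angle at the Cα triple
6.33b–6.47b–6.59b (vertex at the PxxG proline 6.47b), in degrees.  An
axis-fit estimator was deliberately not used for the primary quantity:
the three-point angle is how the quantity is defined in the comparisons
this package reproduces, it is invariant under rigid motion, and an
axis fit would smooth over the local bend being measured.

**Contacts.**  Hydrogen-free geometric criteria (defaults, all
configurable and echoed in every report): hydrogen bond = N/O/S
heavy-atom pair ≤ 3.5 Å; salt bridge = Lys/Arg/His side-chain N vs
Asp/Glu side-chain O ≤ 4.0 Å (takes precedence when both apply);
hydrophobic = side-chain C–C ≤ 4.5 Å; intra-chain pairs closer than 4
residues in sequence are ignored.  Absolute contact counts are
criteria-dependent, so only relative statements (peptide-bound > ligand
free) are treated as robust conclusions; the counts themselves are
reported with their criteria attached.

**Conserved networks.**  Motifs ship as a structured catalog (members,
expected pairwise contacts with their kind, allowed residue types).  A
network's status is the fraction of expected pairs present; "intact"
means fraction ≥ 0.5 by default.  The threshold is a reconstruction —
network "breakup" is described qualitatively in the literature — so the
raw fraction is always reported next to the flag.  Expected pairs are
hub-centred (T6.42b for HETY, R6.37b for the cytoplasmic network)
because those are the members whose release accompanies Gs coupling.

**Interfaces and buried area.**  The receptor–G-protein interface is
summarised as typed contact records plus buried surface area
(SASA_receptor + SASA_partner − SASA_complex)/2, computed with a
deterministic Shrake–Rupley implementation: Fibonacci-sphere sampling
(960 points per atom by default), probe 1.4 Å, radii C 1.70, N 1.55,
O 1.52, S 1.80 Å.  The implementation is validated against the analytic
isolated-sphere area (≤2 % at 960 points) and a 10⁴-point refinement on
overlapping spheres (≤3 %).

**Pocket occupancy.**  After superposing the ligand-free model onto the
peptide-bound reference, a loop heavy atom "occupies" the pocket when it
lies within 4.5 Å (configurable; no published criterion exists) of any
peptide heavy atom.  Counts are monotone in the cutoff.

**State calling.**  The caller is a deliberate reconstruction of the
narrative state model, not a published algorithm, so `indeterminate` is
a first-class outcome: both base networks intact → inactive; both
broken with a Gα chain contacting the receptor → transitional (no
peptide engaged) or active_like (peptide engaged); any other evidence
combination → indeterminate.  The TM6 kink is reported as evidence but
not used as a feature: ligand-free kink angles are receptor-specific
(≈98° GLP-1R vs ≈148° GIPR), so no angle threshold separates states
across receptors.  Peptide-bound structures lacking G protein (e.g.
intermediate-state depositions) land in inactive/indeterminate by these
rules, which matches their intracellularly closed conformation.

## The synthetic generator

The generator emulates exactly the features the pipeline measures, with
ground truth known by construction:

- ideal α-helices (rise 1.5 Å, 100°/residue, Cα radius 2.3 Å — textbook
  geometry, adequate for Cα metrology) arranged as a 7-helix bundle on a
  10 Å circle, residue-numbered by the real receptor tables so the
  shipped numbering applies unchanged; H8 as a short arm off TM7; loops
  as interpolated arcs;
- kink planting: the extracellular part of TM6 is rotated about the
  6.47b vertex onto the cone of directions making exactly the target
  three-point angle with the 6.33b arm; the free cone azimuth is then
  solved by a deterministic 1-D root-find (dense bracket + Brent) to
  satisfy simultaneously a tip-displacement or cross-receptor
  separation target.  Planted angles are exact to floating point;
- displacement planting: whole or half helices are translated rigidly;
  superposing on the untouched helices is then the identity, so the
  measured shift equals the planted magnitude exactly;
- contact planting: each residue carries at most one polar and one
  apolar pseudo-side-chain atom, named as real atoms of real residue
  types so the criteria code runs unmodified; intact pairs are placed at
  2.9 Å (polar) / 4.0 Å (apolar), broken members point away from the
  bundle and the generator verifies ≥4.6 Å clearance (above every
  cutoff) for every expected pair, raising on violation rather than
  emitting a wrong truth file;
- the near-identity comparison (ligand-free vs ago-PAM-bound receptor)
  is emulated by a correlated twin with isotropic Gaussian coordinate
  noise σ = 0.53/√3 Å, which makes the expected Cα RMSD 0.53 Å.

The emulation set plants the printed study-condition magnitudes: kink
angles 98°/112° (GLP-1R free/bound), ~120°/120° (GCGR), 148°/113°
(GIPR); cytoplasmic TM6 shifts 11.9/14.1/10.9 Å at 6.37b; extracellular
movements upon peptide binding 6.5/4.8/6.2 Å (GLP-1R at
1.33b/6.59b/7.33b), 4.8/9.1/5.3 Å (GCGR at 1.34b/6.57b/7.33b),
10.1/10.9/8.1 Å (GIPR at 1.30b/6.55b/7.33b); ligand-free ECL3 tip
separations ~10 Å (GLP-1R–GCGR) and 21 Å (GLP-1R–GIPR); network
integrity per state; a 3-vs-9-contact interface ordering
(free < bound); and GCGR-ECL2 / GIPR-ECL3 pocket occupancy with GLP-1R
loops clear of the pocket.  GIPR's 4.5 Å free-vs-bound intracellular
TM6 offset is planted as one rigid translation, so the companion
measurement at 6.42b also reads 4.5 Å (the separately printed 4.6 Å at
6.42b is not independently plantable by a rigid motion; both
measurements are reported honestly).

What the fixtures do **not** emulate: real side-chain stereochemistry,
backbone connectivity through loops, Ramachandran validity, density
quality, or the conformational heterogeneity of real depositions.
Passing the planted-truth suite therefore demonstrates the correctness
of the measurement machinery, not the biological calibration of the
cutoffs; on real models the contact cutoffs matter and are reported
with every number.

## Problem sizes and numerical choices

A fixture bundle is ~350 residues / ~400 heavy atoms, so the full
pipeline on the nine-state emulation set runs in seconds; the
acceptance script uses 20 reseeded noisy trios (σ = 0.08 Å) for the
classification-stability figure and 960-point SASA throughout.
Noise-free planted recoveries are asserted to 10⁻⁶ (angles, Å);
noisy-recovery tolerances are 1° and 0.1 Å.  Degenerate inputs raise
typed errors (collinear Kabsch input, <3 matched atoms, missing Cα,
unresolvable motif member, >99999-atom PDB writes); the report runner
records per-row failures instead of aborting, and report files are
byte-identical across reruns on identical inputs.

## Known limitations

- Accession-based checks need pre-downloaded files; nothing is fetched.
- The state caller's thresholds (network fraction 0.5, contact cutoffs)
  are reconstructions; on real structures borderline cases will land in
  `indeterminate`, by design.
- Buried-area values depend on the fixed radii table and point count;
  they are comparable within a run, not against other software's
  defaults.
- The GIPR ligand-free TM6 shift (10.9 Å) lacks a published inactive
  GIPR reference frame; in the emulation it is planted against the
  generated inactive bundle, and on real data the choice of reference
  must be stated alongside the number.
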