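# Methods

This note documents the models and conventions behind each computation, the
parameters that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Input model and validation

An alignment row is one of three roles: `structure` (experimental
coordinates), `model` (coordinates from modelling, tagged `structureM` in
PIR), or `sequence` (no coordinates). PIR/ALI input follows the
comparative-modelling convention — a `>P1;id` header, a colon-separated
description whose first field carries the role, and a `*`-terminated body —
and a simplified dialect with only the role field populated is accepted.
Both `-` and `.` are read as gaps; `-` is always written.

Structures are paired with rows by identifier equality (`seq_id` ==
PDB file stem); there is no fuzzy matching. The ungapped row must equal the
*observed* (ATOM-record) one-letter sequence of the chain — mismatches are
reported with the first offending position and both letters, because
submitting the SEQRES sequence (which includes unresolved residues) is the
classic failure mode. `X` in the alignment matches any structure residue, a
pragmatic allowance for nonstandard residues. Automatic rectification of PDB
quirks is deliberately minimal and explicit: first alternate location kept,
selenomethionine (MSE, even as HETATM) read as Met, waters dropped; anything
else fails loudly. The 25-row limit is a validated default, not a constant.

## Solvent accessibility and burial

Shrake–Rupley sampling on probe-expanded spheres (probe 1.4 Å, default 256
points per atom). The sample points come from a golden-section spiral — a
fixed deterministic point set — so all geometric outputs are bit-identical
across runs without any seed. Van der Waals radii: C 1.70, N 1.55, O 1.52,
S 1.80 Å (1.70 default). SASA is computed on the chain *in isolation*
(partner chains would otherwise occlude interface residues and conflate
burial with interface membership). Relative accessibility divides by the
theoretical maximum area of residue X in an extended Gly-X-Gly tripeptide
(Tien et al. 2013 theoretical values, swappable in `config.py`); burial is a
strict `rel < 7%`, so exactly 7.0% is exposed.

## Secondary structure

Hydrogen bonds are detected with the Kabsch–Sander electrostatic energy
E = 0.084·332·(1/d(ON) + 1/d(CH) − 1/d(OH) − 1/d(CN)) kcal/mol, bond when
E < −0.5, amide H rebuilt 1 Å from N anti to the preceding carbonyl;
no H exists for the chain start, prolines, or across chain breaks
(C–N > 2.5 Å). Patterns: two consecutive i→i+4 turns give an α-helix (H,
minimum 4 residues by construction); parallel/antiparallel bridge ladders of
length ≥ 2 give strands (E), with bridge partners at sequence separation
≥ 3; two consecutive i→i+3 turns give 3₁₀ (G) on residues not already H/E.
Priority H > E > G matches the common convention. π-helices, bends, turns,
and cis-peptides are out of scope; the four classes H/G/E/C are exactly what
the typesetting distinguishes. On ideal-geometry fixtures the assignment is
verified residue-for-residue against an independent full DSSP implementation
(mdtraj) in the test suite.

## Torsions and sidechain hydrogen bonds

φ/ψ are standard IUPAC torsions in (−180°, 180°], undefined at termini,
missing atoms, or chain breaks; the italics flag is `φ > 0`. Sidechain
donor/acceptor atoms are tabulated per residue type (Ser/Thr/Tyr hydroxyls
both donate and accept; Asn/Gln split between OD1/OE1 and ND2/NE2; Asp/Glu
carboxylates accept; Lys/Arg/Trp donate; His does both). The criterion is a
3.5 Å donor–acceptor distance to any *other* residue's mainchain N (amide
flag, bold) or O (carbonyl flag, underline); a donor–H–acceptor angle > 90°
is additionally required only when an explicit hydrogen is present, which
heavy-atom structures never have, so the distance test is operative.

## Residue depth

Depth is the mean over a residue's heavy atoms of the minimum distance to
the solvent-accessible surface, where the surface is discretized as the set
of *retained* (unoccluded) sample points of the accessibility computation.
This sampled-surface approximation replaces an exact Euclidean distance
transform: it is deterministic, reuses the SASA machinery, agrees with a
brute-force nearest-surface-point scan by construction, and converges to the
continuous definition as the point count grows. A fully exposed atom has
depth ≈ r_vdw + probe (exactly that for an isolated atom), which is the
lower bound of the scale; the renderer normalizes depth per job to 8 grey
levels. The pocket-detectability metric based on multi-radius probing is not
implemented; the grey background channel always carries depth.

## Contacts and interfaces

Two residues of the same chain are in contact when their minimum heavy-atom
distance is ≤ 6.0 Å (neighbours included — nothing in the definition excludes
them); the implementation uses a k-d tree and is tested for exact equality
with the O(n²m²) all-pairs scan. Interface membership uses 5 Å minimum
heavy-atom distance to another chain of the same file or to a non-water
hetero group, computed on the coordinates as given (no assembly expansion,
no external database). When several partners qualify, the nearest one is
reported — a deterministic rule for the one-bar-per-residue rendering limit.

## Entropy

S_i = −Σ_{a=1..20} f_{i,a} log_n f_{i,a} + f_{i,gap}, with all N rows in the
denominator, gap frequency added linearly, n = min(20, N), and 0·log 0 = 0.
The sum term carries the minus sign so that the stated bounds hold: 0 for a
totally conserved ungapped column, 1 when all residues differ. `X` counts in
the denominator but not in the 20-term sum. N = 1 is defined as 0 (the log
base would be degenerate). The value is clamped to [0, 1] against
floating-point drift. Symbols: `*` iff S = 0; otherwise the half-open
intervals (0, 0.1] → `0`, (0.1, 0.2] → `1`, … (0.9, 1] → `9`.

## Consensus, identity

The consensus row considers all structure- and model-role rows (models have
assigned secondary structure, so they participate); the denominator is the
number of participants, so a gap dilutes the consensus. `a`/`b`/`3` is
emitted when the H/E/G fraction reaches 0.70; at most one class can reach
70%, so no tie-break is needed. PID between two rows is 100 × matches /
columns where both hold a residue, one decimal; with zero shared columns it
is reported as 0 with a flag (the shared-column count).

## Superposition and per-column RMSD

Structures are fitted simultaneously over the columns where *every*
structure has a Cα (≥ 3 required): an initial unit-weight Kabsch fit onto
the first structure, then iterated — per-column variance about the mean
coordinate, weights w_j = 1/(var_j + ε) with ε = 10⁻⁶ Å², weighted Kabsch of
each structure onto the running mean — until the mean moves < 10⁻⁶ Å (≤ 100
iterations). The inverse-variance weights implement the maximum-likelihood
rationale of down-weighting flexible regions instead of excluding them by a
distance cutoff; the full likelihood machinery (hierarchical covariance
priors, rotation sampling) is not reproduced. The iteration is a fixed-point
scheme, not a global optimizer: it locks onto the dominant rigid core, which
is the behaviour the annotation needs, and the hinge fixture is built with a
majority core (20 of 30 residues) so that basin is the one found.

Column RMSD is the all-pairs form, √(mean over unordered pairs of squared
inter-Cα distance), chosen over deviation-about-the-mean because it reduces
to the familiar pairwise RMSD for two structures; it is defined wherever at
least two structures occupy the column (not only on the all-shared set).
Bins are [0,2), [2,4), [4,6), [6,8), [8,∞) Å, rendered as five
increasing-height block glyphs.

## Prediction tracks

Predictions are inputs, not computed — producing them requires sequence
databases and external predictors. Two dialects are read: the `.ss2` table
(fixed column order index/residue/state/coil/helix/strand) and a named-header
TSV (`index residue helix strand coil disorder`) that makes synthetic tracks
trivial. Disorder given as a real in [0, 1] is mapped to the 0–9 integer
scale by ⌊10·conf⌋ capped at 9; Python ints pass through unchanged.
Rendering: the dominant of helix/strand picks the family, ≥ 0.7 strong,
[0.3, 0.7) weak, an exact tie renders nothing; disorder shows from 8. Only
the first plain-sequence row plus every model-tagged row are eligible.

## The annotation XML

One document per job: provenance (tool, release, every parameter), the
alignment with per-residue feature attributes, the column track, the
superposition transforms and final weights, and the identity table. The
vocabulary is this package's own, defined and frozen in
`annotation_schema.xsd`; documents carry a format-version attribute and are
schema-validated on read (ranges included, e.g. entropy must be in [0, 1]).
Floats serialize at six significant digits and round-trips are lossless at
that precision: `write(read(write(d))) == write(d)` byte-for-byte.

## Rendering

Pure function of the document — identical documents give identical bytes.
Alignment blocks wrap at 60 columns; each block shows a ruler, one row per
sequence, then the entropy, consensus, and RMSD rows. Hover-style details
are emulated by a `data-feat` attribute on every glyph listing the features
textually (parseable back, tested); the print variant drops these attributes,
the format key, and the ink-hostile backgrounds. Taylor hues are the
canonical published values, frozen in `config.py`. Everything (CSS included)
is inline: the file renders offline.

## Synthetic generators

All generators are pure functions of their arguments. Backbones are built by
natural-extension placement from ideal bond geometry (N–Cα 1.458, Cα–C
1.525, C–N 1.329, C=O 1.231 Å; N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°;
ω = 180°), with Cβ placed symmetrically off the backbone plane. The
two-strand antiparallel sheet is assembled from a canonical-frame extended
strand (φ = −139°, ψ = 135°) and its two-fold-rotated copy, whose rigid
offset is found by a deterministic grid search maximising well-oriented
inter-strand N–H···O pairs near 2.9 Å; the turn is left as a numbering break.
Toy dimers and ligand complexes are calibrated by bisection so the minimum
heavy-atom separation equals the requested value to 0.01 Å. Random
alignments draw per-column from a stated conservation profile (conserved /
all-different / uniform / alternating) with an explicit seed, and can attach
one ideal helix per row with Gaussian coordinate noise (default test jobs
use 4 rows × 30 columns, σ = 0.3 Å). The hinge pair is a 30-residue helix
duplicated with its last 10 residues translated 10 Å.

These fixtures emulate geometry exactly but not real data's messiness: no
missing atoms or density gaps, no alternate conformations beyond the parser
tests, no realistic sidechains (a polar atom is placed explicitly where a
test demands a donor), and sequence columns are i.i.d. rather than
phylogenetically correlated. Passing tests therefore demonstrate
correctness of the computations and formats, not robustness to pathological
real-world PDB files beyond the handled cases.

## Problem sizes and determinism

Test fixtures are 1–30 residues and ≤ 25-row alignments; the sphere-sampling
default of 256 points per atom keeps a full job below a second while staying
within ~2% of dense-sampling surface areas on the test systems. Every
randomized path (toy alignments, noise) takes an explicit integer seed; the
geometry stack is seed-free and deterministic, which is what makes the
byte-identical-output guarantees of the XML writer and renderer possible.
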