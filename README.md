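# strucaln

Structural annotation and HTML typesetting of sequence–structure alignments.

Comparative analysis of protein families is far more informative when the
multiple sequence alignment (MSA) is read together with the 3-D structures of
its members: whether a residue is buried, helical, hydrogen-bonded to the
backbone, deep in the core, or sitting on an interface constrains which
substitutions are plausible and which alignment columns are trustworthy.
`strucaln` post-processes an MSA (it does not align) in which some rows carry
known structures, computes a standard battery of per-residue and per-column
structural features, stores everything in a lossless XML container, and
typesets a self-contained annotated HTML alignment for visual analysis — the
classic workflow for comparative modelling, construct design, and protein
evolution studies.

## What is computed

**Per residue** (for every row backed by a PDB chain):

- **Solvent accessibility** by Shrake–Rupley sphere sampling; relative
  accessibility is the residue SASA over its maximal area in an extended
  Gly-X-Gly tripeptide, and residues with rel. SASA < 7% are *buried*
  (typeset in UPPERCASE).
- **Secondary structure** from backbone hydrogen-bond energies in the
  Kabsch–Sander style, E = 0.084·332·(1/d(ON) + 1/d(CH) − 1/d(OH) − 1/d(CN))
  kcal/mol with a bond below −0.5: α-helix (red), 3₁₀ helix (maroon),
  β-strand (blue).
- **Mainchain φ sign** (positive φ → italics), **sidechain→mainchain hydrogen
  bonds** (to amide N → bold, to carbonyl O → underline, 3.5 Å donor–acceptor).
- **Residue depth**: mean distance of the residue's atoms to the sampled
  accessible surface, shown as a grey background gradient (darker = deeper).
- **Inter-residue contacts** (heavy-atom minimum distance ≤ 6.0 Å) and
  **chain/ligand interfaces** (≤ 5 Å to another chain or a non-water hetero
  group), shown as coloured bars.

**Per alignment column**:

- **Normalized gap-aware Shannon entropy**
  S_i = −Σ_{a=1..20} f_{i,a}·log_n f_{i,a} + f_{i,gap} with n = min(20, N),
  bounded in [0, 1]; displayed as `*` for S = 0 and `0`–`9` over 0.1
  intervals.
- **Secondary-structure consensus** at a 70% threshold (`a`/`b`/`3` rows).
- **Per-column Cα RMSD** after an iterative inverse-variance-weighted
  multi-structure superposition (flexible columns are down-weighted rather
  than excluded), binned at 2/4/6/8 Å and drawn with five increasing-height
  block glyphs `_ ▂ ▄ ▆ █`.
- **Percentage sequence identity** of the first non-structure row to each
  structure, listed after the alignment.

Rows without structures are coloured by the Taylor physicochemical scheme and
can carry externally produced secondary-structure/disorder prediction tracks
(rendered at the 0.7/0.3 confidence thresholds, disorder from 8 on the 0–9
scale).

## Worked example

Generate a synthetic demonstration job (three noisy helical structures plus
one plain sequence) and annotate it:

```sh
strucaln fixtures --out-dir demo --seed 3
strucaln annotate demo/alignment.pir --pdb-dir demo --out-dir demo_out
```

`demo_out/` then contains the normalized PIR alignment, the superposed-PDB
archive (`superposed.zip`), the annotation XML, and the annotated HTML in
both screen and print variants. The same job through the library:

```python
import pathlib
from strucaln import (parse_pir, parse_pdb_chain,
                      match_alignment_to_structures, run_job,
                      AnnotationParams)

aln = parse_pir(pathlib.Path("demo/alignment.pir").read_text())
structs = [parse_pdb_chain(pathlib.Path(f"demo/seq{i}.pdb").read_text(),
                           "A", source_id=f"seq{i}") for i in (1, 2, 3)]
aln = match_alignment_to_structures(aln, structs)
doc = run_job(aln, AnnotationParams())
print("entropy row:", "".join(c.entropy_symbol for c in doc.columns))
print("PID table  :", doc.pid_table)
```

prints

```
entropy row: *7*9*9*9*9*9*9*7*9*9*9*9*9*7*9
PID table  : [('seq1', 50.0), ('seq2', 53.3), ('seq3', 50.0)]
```

The fixture alternates fully conserved columns (entropy symbol `*`) with
uniformly random ones (symbols `7`–`9`, near-maximal variability among four
sequences), and the plain sequence matches each structure at about half of
the shared columns. Per-residue features are on each row's annotation track,
e.g. residue 6 of `seq1` is helical, 23.7% exposed (not buried), at depth
3.21 Å.

## Layout

- `src/strucaln/seqstruct_io.py` — FASTA/PIR/PDB parsing, validation, PIR/PDB writing
- `src/strucaln/structure_features.py` — per-residue features
- `src/strucaln/alignment_features.py` — entropy, consensus, PID, superposition, RMSD
- `src/strucaln/prediction_tracks.py` — prediction ingestion and render classes
- `src/strucaln/annotation_model.py` — the XML container (+ `annotation_schema.xsd`)
- `src/strucaln/renderer.py` — HTML typesetting
- `src/strucaln/synthetic_fixtures.py` — deterministic test-input generators
- `src/strucaln/cli.py` — `strucaln` command (annotate / render / validate / fixtures)
- `docs/methods.md` — models, conventions, and numerical choices
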