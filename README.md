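# ssapkit

Structural comparison and screening toolkit for single-strand annealing
protein (SSAP)-like folds. It implements, as a reusable pipeline:

- **structio** — PDB reading/writing, per-residue confidence from the
  B-factor column, and mean-confidence quality filtering (models with
  mean confidence strictly below 70 are removed).
- **superpose** — Kabsch superposition, the TM-score
  (`d0 = max(0.5, 1.24·(L−15)^⅓ − 1.8)`), and a deterministic
  TM-align-style heuristic pairwise aligner (gapless + secondary-
  structure seeds, iterative superpose → score matrix → dynamic
  programming with gap open −0.6). Both TM normalizations are reported.
- **secstruct** — Cα-geometry secondary-structure assignment (P-SEA-style
  distance / pseudo-dihedral windows) and helix/strand residue counts
  inside annotated β-sheet / β-hairpin motif spans, transferred from a
  representative through a structural alignment.
- **phylo** — all-vs-all TM similarity matrices, average-linkage (UPGMA)
  dendrograms with Newick export, medoid representative selection, and a
  BLOSUM62 identity×coverage sequence similarity matrix.
- **classify** — screening against representatives (TM normalized by the
  representative's length), tier assignment
  (below < 0.5 ≤ moderate ≤ 0.7 < high) and threshold/min-representative
  tallies, plus two-representative scatter tables.
- **oligomer** — ring/filament assembly by superposing a monomer onto
  every chain of a template, and steric clash counting (distinct heavy
  atoms of a reference copy strictly within 2 Å of an adjacent copy,
  spatial-hash implementation).
- **synthetic_data** — deterministic generators: idealized monomers
  (3-stranded sheet + crossing helix + hairpin with optional helix),
  perturbed families with ground-truth manifests, fragments, 11-mer ring
  templates, and self-avoiding coil decoys. Five presets span the
  distinct helix/strand length regimes of the five fold families.
- **cli** — a `typer` CLI orchestrating the stages.

## CLI

```sh
# generate the bundled synthetic demo set (5 families × 10 members + 5 decoys)
ssapkit simulate demo/ --members 10 --decoys 5 --seed 1

# full pipeline: filter → all-vs-all → tree → representatives → screen →
# tally → motif composition (k=10: one cluster per family + per decoy)
ssapkit run-all demo/ out/ --k 10 --seed 1

# individual stages
ssapkit filter demo/ out/filter.tsv --threshold 70
ssapkit align demo/ out/alignments.tsv
ssapkit cluster demo/ out/tree.nwk
ssapkit represent demo/ out/clusters.tsv --k 4
ssapkit screen demo/ out/screen.tsv --rep rad52-long_m005 --rep sak3-like_m004
ssapkit ring demo/ rad52-long_m000 out/ring.json --copies 11
```

All outputs are plain-text TSV / JSON / Newick with a commented metadata
header (version, seed, normalization choices); reruns with identical
inputs are byte-identical.

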