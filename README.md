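# spatialmtr

Spatially derived missense tolerance ratio (MTR) scoring for protein
structure models, with a clinical-variant validation suite.

## The problem

Population sequencing cohorts let us ask, residue by residue, whether a
protein position tolerates missense change: positions under purifying
selection are depleted of missense variants relative to the synonymous
variation at the same locus, which controls for the local mutation rate.
The missense tolerance ratio captures this as

```
MTR_i = [ mis_obs_i / (mis_obs_i + syn_obs_i) ] / [ mis_exp_i / (mis_exp_i + syn_exp_i) ]
```

where the observed counts come from cohort variant tables and the expected
counts from exhaustively mutating each codon to all 9 possible
single-nucleotide variants and classifying each change under the standard
genetic code.  `MTR = 1` means the neutral expectation; `MTR < 1` means
missense depletion (constraint); `MTR > 1` means missense excess.

`spatialmtr` aggregates these counts over *spatial* windows: for each
residue, all residues whose Cα atoms lie within a fixed radius (5, 8, 11 or
14 Å by default) contribute their counts, so the score reflects selection
on a residue's three-dimensional environment.  Structure models carry
per-residue confidence (pLDDT, 0–100) in the Cα B-factor field, as
AlphaFold2 models do, and the package evaluates scores stratified by that
confidence.  Windows whose combined observed variant total is below 5 are
flagged invalid rather than scored.

It is aimed at structural bioinformaticians evaluating residue-level
constraint scores: it computes the scores, runs the standard validation
battery against pathogenic/benign variant labels (intolerance enrichment
fold change, pooled two-proportion z-test, Mann–Whitney U, ROC AUC with the
low-score ⇒ pathogenic orientation, pLDDT stratification, Pearson
correlation, per-class ECDFs), and generates fully synthetic fixtures with
planted selection signal for end-to-end testing.

## Worked example

Generate a synthetic study — a 200-residue idealized helix whose residues
40–60 form an intolerant span (90% of missense observations removed at a
cohort depth of 20 per residue) with 150 planted clinical labels — then
score and validate it:

```bash
spatialmtr simulate demo --seed 1
spatialmtr score demo/model.pdb demo/cds.fasta demo/observed.tsv demo/scores.tsv
spatialmtr validate demo/scores.tsv demo/labels.tsv demo/report.json --radius 8
```

The score table has one row per residue per radius:

```
protein_id  transcript_id  residue_index  aa  radius  mtr       valid  w_mis_obs  w_syn_obs  w_mis_exp  w_syn_exp  n_window  plddt
model       SIMTX200       1              M   5       1.028571  1      12         2          15         3          2         90.00
model       SIMTX200       50             C   5       0.360902  1      2          5          19         5          3         90.00
```

Residue 1 (outside the span) sits at the neutral expectation (MTR ≈ 1.03);
residue 50, in the suppressed span, is strongly depleted (MTR ≈ 0.36 at
5 Å).  The validation report recovers the planted signal:

```
score   benign_intolerant  benign_total  benign_pct  pathogenic_intolerant  pathogenic_total  pathogenic_pct  fold_change  auc
scores  3                  46            6.52        13                     50                26.0            3.99         0.896
```

Pathogenic labels are 3.99× enriched below the intolerance threshold of
0.5, the AUC for predicting pathogenicity from (low) MTR is 0.896, and the
accompanying JSON carries the test statistics (here Mann–Whitney
p = 2.4e-11, two-proportion z-test p = 0.011) plus pLDDT-stratified
sub-reports and the de novo vs. non-de novo comparison.

Other subcommands: `spatialmtr expected` writes the per-residue mutational
opportunity table for a CDS, and `spatialmtr paint` writes scores into the
B-factor column of a PDB copy (invalid residues get the out-of-band
sentinel 999.99) for coloring in any structure viewer.

Everything is also available as a library, e.g.:

```python
from spatialmtr import load_structure, build_windows, window_size_stats
model = load_structure("demo/model.pdb")
window_size_stats(build_windows(model, 8.0))
# {'mean': 8.9, 'median': 9.0, 'histogram': {...}}
```

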