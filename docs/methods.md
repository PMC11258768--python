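# Methods

## The score

For residue *i* of a protein with a structure model, let *W(i)* be the set
of residues whose Cα atoms lie within radius *r* of residue *i*'s Cα
(boundary inclusive; *i* ∈ *W(i)* always).  Over the residues of *W(i)*
four counts are summed: observed missense and synonymous variants from
population cohorts, and expected missense and synonymous changes from
exhaustive single-nucleotide mutagenesis of the underlying codons.  The
score is the ratio of observed to expected missense fractions:

    MTR_i(r) = [Σ mis_obs / (Σ mis_obs + Σ syn_obs)]
             / [Σ mis_exp / (Σ mis_exp + Σ syn_exp)]

Synonymous counts act as the mutation-rate control: a window with few
missense variants but also few synonymous ones is poorly sampled, not
constrained.  Values are reported uncapped; 1 is the neutral expectation.

Assumptions worth stating plainly: the model treats every possible SNV of
a codon as equally likely (no mutational-spectrum weighting, no CpG
adjustment), treats distinct observed variant sites as the unit of
observation (allele frequencies do not enter), and assumes the structure
model's residue numbering matches the translated CDS exactly.

## Window construction

- Distance convention: Cα–Cα Euclidean distance, with membership at
  distance ≤ r.  Cα is the one atom guaranteed present in every modeled
  residue, making the definition total; windows are symmetric by
  construction.  Neighbor search uses a k-d tree and is verified in the
  test suite against an all-pairs oracle.
- Radii: 5, 8, 11 and 14 Å by default.  Smaller windows are more local but
  capture fewer variant counts; larger windows trade spatial resolution for
  statistical power.
- Single chain only: when a file has several chains the first chain with
  Cα atoms (or a named chain) is used; windows never cross chains.
- Residues without a Cα atom are dropped from the model with a logged
  warning; they belong to no window and receive no score.

## Count construction

- Expected counts: each codon contributes its 9 possible SNVs, classified
  under the standard genetic code (NCBI table 1).  Nonsense and stop-lost
  changes belong to neither class, so per codon mis_exp + syn_exp ≤ 9.
- Observed counts: cohort tables are validated against the transcript
  (reference nucleotide and consequence must agree with the codon) and
  deduplicated by default, counting each distinct
  (residue, codon position, alternative nucleotide) site once however many
  cohorts report it (`mode="sum"` counts every record instead).  This
  presence/absence convention is the standard one for tolerance-ratio
  scores; allele counts would conflate constraint with frequency.
- Transcript ↔ model mapping is identity-only: any sequence discordance is
  an error naming the first mismatching position.  No alignment heuristics.

## Validity filter

A residue's score at radius r is valid only if the window's combined
observed total (missense + synonymous) is at least `min_obs` (default 5)
and no denominator is zero (an all-nonsense window with mis_exp = 0 is
invalid, not infinite).  Invalid scores are written as `NA` with
`valid = 0` rather than dropped, so coverage accounting is reproducible
from the score table alone.

## Validation statistics

- Intolerance enrichment: a variant is "in a region of intolerance" when
  its residue's score is below a threshold (default 0.5).  The fold change
  is (pathogenic% below) / (benign% below); +inf when only the benign cell
  is empty, NaN (undefined) when both are.
- Two-proportion z-test: pooled variance, two-sided, no continuity
  correction; undefined (NaN) when the pooled proportion is 0 or 1.
- Mann–Whitney U: exact null distribution for samples of ≤ 20 without
  ties, otherwise the tie-corrected continuity-corrected normal
  approximation (scipy).
- AUC: computed by the rank (Mann–Whitney) identity with the fixed
  orientation that a low score predicts pathogenicity —
  AUC = P(score_path < score_benign) + ½ P(equal).  The orientation is not
  auto-detected; auto-detection would silently flip on null-like data.
- Clinical-label filter: missense consequence, ≥ 2 review stars, no
  conflicting interpretations — the conventional reliability bar for
  ClinVar-style labels.
- pLDDT bands: high (70, 100], medium [50, 70], low [0, 50) on the native
  0–100 scale, with both boundary values assigned to the medium band (a
  documented tie rule; the bands are conventionally quoted as "> 70 good,
  < 50 poor", which leaves the boundaries unspecified).
- Multi-model proteins: when several models of one protein each yield a
  score track, per-site means over valid scores give a single track
  (`aggregate_site_scores`); model selection prefers the highest mean
  pLDDT, ties broken by input order.

## The synthetic generator

The generator emulates the statistical structure the score relies on, not
biophysics:

- Geometry: an idealized helical Cα trace, Cα_i = (r cos((i−1)θ),
  r sin((i−1)θ), i·d) with r = 2.3 Å, d = 1.5 Å, θ = 100°, giving the
  canonical ~3.8 Å consecutive-Cα spacing.  An optional "disordered tail"
  re-lays the last k residues as an extended chain (3.8 Å rise) with low
  pLDDT, emulating low-confidence termini whose windows capture few
  residues.
- Sequence: ATG followed by uniform random sense codons (no internal
  stops).
- Cohort: per residue, Poisson(depth) draws with replacement from the
  codon's possible missense+synonymous SNVs; inside the intolerant span,
  missense draws are thinned with probability `suppression`.  Poisson
  counts with thinning is the simplest model matching the
  missense-depletion narrative.
- Labels: half pathogenic, half benign; a pathogenic label lands in-span
  (and a benign label out-of-span) with probability 1 − leakage, so
  leakage 0.5 is a positional null.  Stars, conflicts, de novo flags and a
  small non-missense fraction are drawn so every downstream filter is
  exercised.

Reference condition (the generator defaults): n = 200 residues, intolerant
span 40–60, suppression 0.9, depth 20, pLDDT 90, 150 labels, leakage 0.1,
seed 42.  Leakage is 0.1 rather than 0 because perfectly span-aligned
labels are unrealistic — benign variants do occur in constrained regions —
and would leave the benign-intolerant contingency cell structurally empty.
All draws are deterministic in (config, seed), with separate
substreams per artifact so changing label parameters does not perturb the
cohort.

What passing tests on this generator do *not* show: real proteins are not
uniform helices (window sizes vary enormously with local fold), real
mutation rates are not uniform across SNVs (CpG transitions dominate),
real cohorts share ascertainment structure across sites, and real ClinVar
labels are not planted by a known mechanism.  The generator demonstrates
correctness of the machinery and recoverability of a known signal, not
field performance.

## Numerical and design choices

- Distinct-variant deduplication is order-invariant (set-based), and score
  tables are written with fixed formatting (`%.6f`, NA tokens, sorted rows)
  so identical inputs give byte-identical outputs.
- Note on the observed-total filter: "fewer than five observed mutations
  combined" is read as the combined missense+synonymous total < 5
  invalidating the window (not either class alone); `min_obs` is
  configurable.
- The painted-PDB sentinel for invalid residues is 999.99, out of band on
  both the MTR and pLDDT scales.
- Degenerate inputs: empty models, single-class label sets, zero-variance
  correlations and absent radii raise typed errors rather than returning
  silent NaNs; the two 0-denominator statistics (z-test, fold change)
  return flagged NaN because callers legitimately reach them with sparse
  data.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
the reference condition (200 residues, ~4,000 cohort records, 150 labels),
with 20-seed replicates for the null calibrations and 20 random 200–500
residue point clouds for the window-oracle equivalence check.  These sizes
give stable statistics (binomial/Poisson standard errors well inside the
asserted bands) while keeping a full run to a few seconds.

## Known limitations

- No mutational-spectrum weighting in the expected counts; scores on real
  data inherit that simplification.
- Identity-only transcript-to-structure mapping: isoform mismatches must be
  resolved upstream.
- Single-chain scoring; inter-chain contacts never contribute counts.
- The windowed ratio is undefined below the observed-count floor, so
  sparse cohorts leave coverage gaps — by design, not by accident.
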