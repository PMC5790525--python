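# Methods

## Scope and model

`neoscout` covers the in-silico arm of neoantigen discovery in a tumor
with known somatic missense variants, and the statistics of a
two-condition sorted-population RNA-Seq comparison. Wet-lab stages that
such studies pair with it (ELISPOT, tetramer staining, vaccination) and
upstream read processing (alignment, RSEM-style quantification, exome
variant calling) are out of scope: the package consumes variant tables,
proteome/CDS FASTA, scoring matrices, and count matrices.

### Variants and peptides

A variant is a single amino-acid substitution `<ref><pos><alt>` in 1-based
protein coordinates, validated against the reference proteome (the stated
reference residue must match). Only missense outcomes are accepted; a
CDS-level substitution is lifted to protein level and rejected as
`synonymous` or `nonsense` otherwise. Selenocysteine and ambiguity codes
are rejected — the 20-letter alphabet covers the intended use.

Candidate epitopes are all k-mer windows of the mutant protein whose span
covers the altered residue, for each length the allele's binding groove
accepts. Defaults follow the canonical preferences of the two C57BL/6
class I alleles: H-2Kb {8, 9}, H-2Db {9, 10}; both are configuration, not
assumptions baked into the code. Each mutant window carries its wild-type
counterpart (identical coordinates, Hamming distance exactly 1), which
downstream serves as the specificity control. Windows are deduplicated by
(allele, peptide, start) within a variant; identical peptides arising from
different variants are kept separate because provenance matters in
reports.

The synthetic-long-peptide designer returns a `total_len`-mer (default 28)
with the mutant residue at offset ⌈total_len/2⌉, shifting only when a
protein terminus forces truncation. Centering is a choice: published SLPs
do not always state the epitope register, and a centered mutation keeps
the most flanking context on both sides for in-vivo processing.

### Binding prediction and consensus

The in-repo predictor is an additive position-scoring matrix:

    log10(IC50 / nM) = intercept + sum_i weights[residue_i, i]

with the result clamped to [0.01, 1e7] nM. The clamp prevents zero
division in the affinity score and overflow for adversarial matrices; it
is recorded in output metadata. The matrix file format is a TSV with
`#allele/#length/#intercept/#predictor` headers and 20 alphabetical
residue rows.

Several predictors (default: a panel of five matrices per allele/length)
score each candidate. The consensus IC50 is the **geometric mean** — the
arithmetic mean of log10 IC50, exponentiated. Rationale: IC50s span
orders of magnitude and the scoring model is additive in log space, so
averaging on the log scale is the natural choice; an arithmetic-mean
consensus is available (`scale="linear"`) for sensitivity analyses. The
consensus is clipped into [min, max] of its inputs to keep the bounding
invariant exact under floating-point round-trip.

### Prioritization

Candidates are ranked by ascending consensus IC50, ties broken by gene
symbol then peptide (chosen purely for deterministic reports), and
reported with the affinity score (1/IC50) × 100, which is rank-equivalent
to the IC50 ordering. Tier membership uses strict `<` at 500/50/25 nM, so
a candidate at exactly 500 nM is excluded; tiers are nested by
construction. The expression screen keeps a candidate when binary
evidence says expressed, or — absent evidence — when TPM ≥ `min_tpm`
(default 1.0, a conventional detection floor standing in for a binary
transcript-confirmation assay). Missing transcripts are an error by
default (`strict`) so silent ID mismatches cannot inflate candidate
lists; `lenient` marks them unexpressed instead. Survivors and rejects
always partition the input.

Manhattan layout: when every candidate has genomic coordinates, x is the
position plus a cumulative per-chromosome offset (chromosomes in sorted
name order); otherwise 1-based candidate index, with a logged warning on
mixed presence.

## RNA-Seq differential expression

TPM is computed from counts and effective lengths,
tpm_g = (c_g/ℓ_g)/Σ_j(c_j/ℓ_j) × 1e6; each sample column sums to one
million by construction. Tests run per gene on log2(TPM + 1) — base and
pseudocount are conventions; the pseudocount keeps zero-TPM genes finite
while barely perturbing well-expressed genes.

The default test is the classical pooled-variance (Student) two-sample
t-test. With equal group sizes and a common within-group variance — the
regime of the balanced designs this module targets and of its simulations
— the pooled t is exactly calibrated even at n = 3/group, whereas the
Welch test is noticeably conservative at such tiny n (empirical type-I
fraction ≈ 0.036 at nominal 0.05). Welch remains available via
`equal_var=False` for unbalanced or heteroscedastic designs. Genes with
zero variance in both groups and equal means get t = 0, p = 1 (rather
than being dropped), so the BH family size always equals the gene count;
constant-but-different genes get p = 0.

BH adjustment is the standard step-up procedure (via
`statsmodels.multipletests`), input order preserved, verified in tests
against an independent brute-force min-over-tail implementation.
Volcano rows floor q at machine epsilon before −log10; significance
flags use strict q < 0.05. The temporal-profile table reports per-day
group means of log2(TPM+1), their difference, whether the difference
increases strictly across days, and the day of maximal difference.

## Synthetic data generator

The generator emulates the study conditions end to end and is the source
of every test fixture. All randomness flows through
`numpy.random.default_rng` (PCG64), so outputs are byte-reproducible for
a fixed seed on any platform.

**Cohort** (defaults: 200 genes of 80–300 residues, 50 variants, 5
predictors): proteins are sampled uniformly over the 20-letter alphabet
and regenerated until all 8-mers within a protein are distinct, so a
mutant window can never coincide with a wild-type substring; CDS are
random synonymous back-translations plus a stop codon. One variant per
gene; the *planted* variant sits at an interior position of gene 0, and
its centered 8-mer window is steered to a target IC50 (default 10 nM)
under a shared "truth" matrix. Each predictor's matrix is the truth
matrix plus i.i.d. N(0, 0.1) entry noise (background weights
N(0, 0.15), intercept 4.5 ≈ 30 µM typical background), so per-predictor
planted IC50s scatter within about an order of magnitude around the
target while the consensus tightens around it — the reason multi-
predictor averaging is worth doing, and an assertable one. A configured
fraction (default 0.2) of non-planted variants gets TPM 0; the planted
transcript is always expressed. Truth files (`truth_*.tsv`) record the
planted peptide and the unexpressed set and are never read by the
pipeline.

**Expression** (defaults: 2,000 genes, 100 induced, log2 effect 1.0,
noise sd 0.15, 4 samples/group, days 11/14/17 with effect ramp
0.4/0.7/1.0): per-gene log2 baselines are N(8, 1.5); each sample's log2
count adds the (ramped) group effect and N(0, noise_sd); counts are
rounded to integers, lengths uniform 500–5000. The noise default (≈10%
CV between replicates) reflects technical plus modest biological
variability of FACS-sorted population RNA-Seq on well-expressed genes;
at that level a 2-fold induction at n = 4/group is recovered after BH
with sensitivity ≈ 0.9. What the generator does **not** emulate:
count overdispersion beyond log-normal noise, gene–gene correlation,
library-composition artefacts beyond the mechanical TPM renormalization,
or low-count discreteness — so passing tests demonstrate the statistics
are implemented correctly under their own assumptions, not that real
tissue data would behave this cleanly.

## Problem sizes and numerical choices

Tests and the acceptance script run at the generator's default scale
(200-gene proteome, 50 variants — about 1,600 windows and 8,000 matrix
evaluations per cohort; 2,000-gene expression matrices), which exercises
every code path in seconds; an exome-scale profile (thousands of
variants) is a configuration change, not different code. Scoring is
vectorised (`predict_ic50_many`) for bulk use. TSV floats are written
with `%.6g` so identical runs are byte-identical.

## Known limitations

- No proteasomal-processing or TAP-transport model: matrix binding
  prediction only. No percentile-rank normalization and no trained
  matrices — matrices are inputs.
- No indel/frameshift/splice-derived peptides; missense only.
- Expression evidence is transcript-level; no allele-specific expression
  or RNA support counting for the variant allele.
- The DE module tests one day at a time (the pipeline reports the last
  day); it does not model day-by-treatment interactions jointly.
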