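# neoscout

Neoantigen discovery from somatic missense variants, plus the companion
bulk RNA-Seq differential-expression statistics — built for tumor
immunogenomics studies in syngeneic mouse models (H-2K^b^ / H-2D^b^
restricted epitopes), but generic over alleles and scoring matrices.

Tumor-specific mutant peptides (neoantigens) arise from nonsynonymous
single-nucleotide variants (nsSNVs) and can be recognized by CD8⁺ T cells
when presented on MHC class I. `neoscout` implements the computational arm
of that discovery workflow:

1. **Variants → mutant proteins.** Somatic missense variants in `P315L`
   notation are validated against a proteome FASTA and applied to the
   reference protein.
2. **Window enumeration.** Every k-mer window covering the altered residue
   is enumerated per allele (defaults: H-2Kb 8/9-mers, H-2Db 9/10-mers),
   each paired with its wild-type counterpart (Hamming distance 1).
3. **Binding prediction.** Each window is scored by a panel of additive
   position-scoring matrices (stabilized-matrix-method family):
   log₁₀ IC₅₀ = intercept + Σᵢ w[aaᵢ, i], IC₅₀ clamped to [0.01, 10⁷] nM.
   The **consensus IC₅₀** is the geometric mean across predictors.
4. **Prioritization.** Candidates are ranked by ascending consensus IC₅₀
   and reported with the affinity score **(1/IC₅₀) × 100**, in nested
   tiers IC₅₀ < 500, < 50, < 25 nM (strict inequalities), with
   Manhattan-plot coordinates when genomic positions are available.
5. **Expression screen.** Candidates whose transcript is not expressed
   (TPM below threshold, or negative binary evidence) are moved to a
   rejects table rather than silently dropped.
6. **Vaccine design.** A synthetic long peptide (default 28-mer) is cut
   around the mutant residue, centered at offset ⌈L/2⌉.

The RNA-Seq module quantifies counts in **TPM**
(tpm_g = (c_g/ℓ_g)/Σ_j(c_j/ℓ_j) × 10⁶), tests each gene with a two-sample
t-test on log₂(TPM+1), and adjusts p-values with **Benjamini–Hochberg**;
temporal-induction and volcano tables come along for multi-day designs.

A fully seeded synthetic-data generator (`neoscout.simulate`) produces
every input the pipeline consumes — toy proteome/CDS, variant tables with
a planted ~10 nM binder, predictor matrix panels, expression tables, and
grouped count matrices with planted induced genes — so the whole stack is
testable end to end without external data.

## Worked example

Simulate a 200-gene tumor with 50 somatic missense variants, then run
discovery:

```sh
neoscout simulate --outdir demo --seed 7
neoscout -v discover \
    --proteome demo/proteome.fasta --variants demo/variants.tsv \
    --matrix-dir demo/matrices --expression demo/expression.tsv \
    --outdir demo/results
```

The stage log shows the discovery funnel:

```
INFO neoscout.pipeline: loaded 50 validated missense variants
INFO neoscout.pipeline: enumerated 1664 mutant peptide windows
INFO neoscout.pipeline: expression screen kept 1320 / 1664 candidates
INFO neoscout.pipeline: 2 candidates below 500 nM
INFO neoscout.pipeline: 1 candidates below 50 nM
INFO neoscout.pipeline: 1 candidates below 25 nM
```

and the top of `demo/results/report_ranked.tsv` recovers the planted
neoantigen (an 8-mer on gene g0000 engineered to bind at ~10 nM) at rank 1:

```
rank  gene   protein_change  allele  consensus_ic50_nM  affinity_score  tier
1     g0000  T126V           H-2Kb   7.81468            12.7964         lt25
2     g0077  K40W            H-2Kb   442.391            0.226044        lt500
```

An IC₅₀ of 7.8 nM is a very strong predicted binder (affinity score
100/7.8 ≈ 12.8); the lt25 tier is the set a study would take forward to
expression screening and T-cell validation. The matching RNA-Seq bundle is
analysed with `neoscout de --counts demo/rnaseq/counts.tsv
--sample-sheet demo/rnaseq/samples.tsv --lengths demo/rnaseq/lengths.tsv
--outdir demo/results_de`, and `neoscout report` renders Manhattan/volcano
PNGs from the written tables.

From Python, the validated mICAM1 worked example:

```python
>>> from neoscout import parse_missense_notation, design_long_peptide
>>> parse_missense_notation("P315L")
MissenseChange(ref_aa='P', position=315, alt_aa='L')
>>> lp = design_long_peptide(protein, position=315, total_len=28)  # 28-mer SLP
>>> len(lp.sequence), lp.mut_offset
(28, 14)
```

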