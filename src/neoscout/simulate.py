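"""Seeded generators for every input the pipeline consumes.

``simulate_cohort`` emulates a tumor exome: a toy proteome (and matching
CDS), a table of somatic missense variants, a panel of matrix predictors,
and a per-transcript expression table.  One variant is *planted*: one of its
mutant windows is engineered to score near a target IC50 (default 10 nM)
under every predictor, while background windows score orders of magnitude
weaker — so an end-to-end run should recover the planted peptide at rank 1.
A fraction of the non-planted variants is marked unexpressed (TPM 0).

``simulate_expression`` emulates the two-condition sorted-population
RNA-Seq design: log-normal per-gene baselines, a multiplicative treatment
effect on a planted gene set, and a day-dependent ramp so the induced
effect grows across time points (maximal at the last day).

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a
fixed seed reproduces outputs byte-for-byte.  Truth files are namespaced
``truth_*`` and are never read by the pipeline itself.

``tumor_volume`` is the caliper-measurement utility L x W^2 / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .binding import ScoringMatrix, write_scoring_matrix
from .epitopes import DEFAULT_ALLELES, MhcAllele, H2_KB
from .expression import ExpressionTable
from .sequence import (
    AMINO_ACIDS,
    MissenseChange,
    ProteinRecord,
    CdsRecord,
    SomaticVariant,
)

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_REVERSE_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_CODON_TABLE.forward_table.items()):
    _REVERSE_CODONS.setdefault(aa, []).append(codon)
_STOP_CODONS = sorted(_CODON_TABLE.stop_codons)

_AA_ARRAY = np.array(list(AMINO_ACIDS))


class ConfigError(ValueError):
    pass


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume in mm^3: L x W^2 / 2 (argument order matters)."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("tumor dimensions must be positive")
    return length_mm * width_mm**2 / 2.0


@dataclass
class DEParams:
    """Two-condition expression simulation parameters.

    ``log2_effect`` is the full (last-day) induction of planted genes on the
    log2 scale; ``ramp`` scales it per day.  ``noise_sd`` is the
    between-replicate standard deviation of log2 expression.
    """

    n_genes: int = 2000
    n_de_genes: int = 100
    log2_effect: float = 1.0
    noise_sd: float = 0.15
    samples_per_group: int = 4
    days: tuple = (11, 14, 17)
    ramp: tuple = (0.4, 0.7, 1.0)
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    groups: tuple = ("control", "anti-PD1")

    def __post_init__(self) -> None:
        if self.n_de_genes > self.n_genes:
            raise ConfigError("n_de_genes cannot exceed n_genes")
        if self.samples_per_group < 2:
            raise ConfigError("need >= 2 samples per group")
        if len(self.ramp) != len(self.days):
            raise ConfigError("ramp must give one multiplier per day")


@dataclass
class SimulationConfig:
    """Cohort simulation parameters (defaults are the small CI-scale profile;
    set ``n_genes``/``n_variants`` up to exome scale for soak runs)."""

    seed: int = 0
    n_genes: int = 200
    protein_length_range: tuple = (80, 300)
    n_variants: int = 50
    planted_target_ic50: float = 10.0
    fraction_unexpressed: float = 0.2
    n_predictors: int = 5
    alleles: tuple = DEFAULT_ALLELES
    matrix_weight_sd: float = 0.15
    predictor_noise_sd: float = 0.1
    intercept: float = 4.5
    de_params: DEParams = field(default_factory=DEParams)

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_variants < 1:
            raise ConfigError("need >= 2 genes and >= 1 variant")
        if self.n_variants >= self.n_genes:
            raise ConfigError("n_variants must be < n_genes (one variant per gene)")
        if not 0 <= self.fraction_unexpressed <= 1:
            raise ConfigError("fraction_unexpressed must lie in [0, 1]")
        if self.n_predictors < 1:
            raise ConfigError("need >= 1 predictor")
        max_k = max(max(a.peptide_lengths) for a in self.alleles)
        if self.protein_length_range[0] < 2 * max_k + 28:
            raise ConfigError(
                "minimum protein length too short for the planted epitope "
                "and long-peptide windows"
            )


@dataclass
class SyntheticCohort:
    """In-memory cohort: all pipeline inputs plus the truth table."""

    config: SimulationConfig
    proteins: dict[str, ProteinRecord]
    cds: dict[str, CdsRecord]
    variants: list[SomaticVariant]
    matrices: list[ScoringMatrix]
    expression: ExpressionTable
    truth: pd.DataFrame

    @property
    def planted(self) -> pd.Series:
        return self.truth[self.truth["record"] == "planted"].iloc[0]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["proteome"] = outdir / "proteome.fasta"
        with open(paths["proteome"], "w") as fh:
            for tx in sorted(self.proteins):
                p = self.proteins[tx]
                fh.write(f">{p.id} gene={p.gene}\n{p.sequence}\n")
        paths["cds"] = outdir / "cds.fasta"
        with open(paths["cds"], "w") as fh:
            for tx in sorted(self.cds):
                c = self.cds[tx]
                fh.write(f">{c.transcript_id} gene={c.gene}\n{c.sequence}\n")

        paths["variants"] = outdir / "variants.tsv"
        rows = [
            {
                "gene": v.gene,
                "transcript_id": v.transcript_id,
                "protein_change": str(v.change),
                "chrom": v.chrom,
                "pos": v.genomic_pos,
                "expressed": "NA",
            }
            for v in self.variants
        ]
        pd.DataFrame(rows).to_csv(paths["variants"], sep="\t", index=False)

        matrix_dir = outdir / "matrices"
        matrix_dir.mkdir(exist_ok=True)
        paths["matrices"] = matrix_dir
        for m in self.matrices:
            name = f"{m.predictor_id}_{m.allele.replace('-', '')}_L{m.length}.tsv"
            write_scoring_matrix(m, matrix_dir / name)

        paths["expression"] = outdir / "expression.tsv"
        self.expression.write_tsv(paths["expression"])

        paths["truth"] = outdir / "truth_cohort.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_protein(rng: np.random.Generator, length: int, window: int = 8) -> str:
    """Random protein whose length-``window`` substrings are all distinct,
    so a mutant window can never coincide with a wild-type substring."""
    while True:
        seq = "".join(rng.choice(_AA_ARRAY, size=length))
        kmers = {seq[i : i + window] for i in range(length - window + 1)}
        if len(kmers) == length - window + 1:
            return seq


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [
        _REVERSE_CODONS[aa][rng.integers(len(_REVERSE_CODONS[aa]))] for aa in protein
    ]
    codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic tumor cohort (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    # --- proteome & CDS -----------------------------------------------------
    lengths = rng.integers(
        config.protein_length_range[0], config.protein_length_range[1] + 1, size=n
    )
    proteins: dict[str, ProteinRecord] = {}
    cds: dict[str, CdsRecord] = {}
    genes, transcripts = [], []
    for i in range(n):
        gene, tx = f"g{i:04d}", f"tx{i:04d}"
        genes.append(gene)
        transcripts.append(tx)
        seq = _random_protein(rng, int(lengths[i]))
        proteins[tx] = ProteinRecord(id=tx, gene=gene, sequence=seq)
        cds[tx] = CdsRecord(transcript_id=tx, gene=gene, sequence=_back_translate(rng, seq))

    # --- variants (one per gene; gene 0 carries the planted neoantigen) ----
    planted_protein = proteins[transcripts[0]].sequence
    max_k = max(max(a.peptide_lengths) for a in config.alleles)
    planted_pos = int(
        rng.integers(max_k + 4, len(planted_protein) - max_k - 4 + 1)
    )
    variants: list[SomaticVariant] = []

    def _random_change(protein: str, pos: int) -> MissenseChange:
        ref = protein[pos - 1]
        alt = ref
        while alt == ref:
            alt = str(rng.choice(_AA_ARRAY))
        return MissenseChange(ref, pos, alt)

    planted_change = _random_change(planted_protein, planted_pos)
    other_genes = rng.choice(np.arange(1, n), size=config.n_variants - 1, replace=False)
    gene_indices = [0] + sorted(int(g) for g in other_genes)
    for gi in gene_indices:
        protein = proteins[transcripts[gi]].sequence
        if gi == 0:
            change = planted_change
        else:
            pos = int(rng.integers(1, len(protein) + 1))
            change = _random_change(protein, pos)
        variants.append(
            SomaticVariant(
                gene=genes[gi],
                transcript_id=transcripts[gi],
                change=change,
                chrom=f"chr{1 + gi % 5}",
                genomic_pos=1_000_000 + (gi // 5) * 100_000 + 3 * change.position,
            )
        )

    # --- planted mutant window (first allele, its shortest length) --------
    planted_allele: MhcAllele = config.alleles[0] if config.alleles else H2_KB
    planted_k = min(planted_allele.peptide_lengths)
    start = min(
        max(1, planted_pos - planted_k // 2 + 1),
        len(planted_protein) - planted_k + 1,
    )
    mut_protein = (
        planted_protein[: planted_pos - 1]
        + planted_change.alt_aa
        + planted_protein[planted_pos:]
    )
    planted_peptide = mut_protein[start - 1 : start - 1 + planted_k]

    # --- predictor matrices -------------------------------------------------
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    matrices: list[ScoringMatrix] = []
    for allele in config.alleles:
        for k in sorted(allele.peptide_lengths):
            truth_w = rng.normal(0.0, config.matrix_weight_sd, size=(20, k))
            if allele.name == planted_allele.name and k == planted_k:
                # steer the shared truth matrix so the planted window hits
                # the target IC50; per-predictor noise spreads it slightly
                rows = [aa_index[aa] for aa in planted_peptide]
                current = config.intercept + truth_w[rows, np.arange(k)].sum()
                delta = (np.log10(config.planted_target_ic50) - current) / k
                truth_w[rows, np.arange(k)] += delta
            for j in range(config.n_predictors):
                w = truth_w + rng.normal(
                    0.0, config.predictor_noise_sd, size=(20, k)
                )
                matrices.append(
                    ScoringMatrix(
                        allele=allele.name,
                        length=k,
                        weights=w,
                        intercept=config.intercept,
                        predictor_id=f"smm{j + 1}",
                    )
                )

    # --- expression table ---------------------------------------------------
    n_unexpressed = round(config.fraction_unexpressed * config.n_variants)
    non_planted = [v for v in variants if v.gene != genes[0]]
    unexpressed_idx = rng.choice(
        len(non_planted), size=min(n_unexpressed, len(non_planted)), replace=False
    )
    unexpressed = {non_planted[i].transcript_id for i in unexpressed_idx}
    tpm: dict[str, float] = {}
    for tx in transcripts:
        if tx in unexpressed:
            tpm[tx] = 0.0
        elif tx == transcripts[0]:
            tpm[tx] = 50.0
        else:
            tpm[tx] = round(float(rng.lognormal(2.0, 1.0)) + 1.0, 3)
    expression = ExpressionTable(tpm=tpm)

    # --- truth table --------------------------------------------------------
    truth_rows = [
        {
            "record": "planted",
            "gene": genes[0],
            "transcript_id": transcripts[0],
            "protein_change": str(planted_change),
            "allele": planted_allele.name,
            "peptide": planted_peptide,
            "window_start": start,
            "target_ic50_nM": config.planted_target_ic50,
        }
    ]
    for v in variants:
        if v.transcript_id in unexpressed:
            truth_rows.append(
                {
                    "record": "unexpressed",
                    "gene": v.gene,
                    "transcript_id": v.transcript_id,
                    "protein_change": str(v.change),
                    "allele": "",
                    "peptide": "",
                    "window_start": "",
                    "target_ic50_nM": "",
                }
            )
    truth = pd.DataFrame(truth_rows)

    return SyntheticCohort(
        config=config,
        proteins=proteins,
        cds=cds,
        variants=variants,
        matrices=matrices,
        expression=expression,
        truth=truth,
    )


@dataclass
class SyntheticExpression:
    """Grouped count matrices across days, with the truth gene list."""

    params: DEParams
    counts: pd.DataFrame  # genes x samples
    sample_sheet: pd.DataFrame  # sample, group, day
    effective_lengths: pd.Series
    de_genes: list[str]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "samples": outdir / "samples.tsv",
            "lengths": outdir / "lengths.tsv",
            "truth": outdir / "truth_de_genes.tsv",
        }
        self.counts.to_csv(paths["counts"], sep="\t", index_label="gene")
        self.sample_sheet.to_csv(paths["samples"], sep="\t", index=False)
        self.effective_lengths.rename("effective_length").to_csv(
            paths["lengths"], sep="\t", index_label="gene"
        )
        pd.Series(self.de_genes, name="gene").to_csv(paths["truth"], sep="\t", index=False)
        return paths


def simulate_expression(params: DEParams, seed: int) -> SyntheticExpression:
    """Simulate grouped RNA-Seq count matrices with planted induced genes.

    Per gene g and sample s: log2 count = baseline_g + effect_g * ramp_day
    (treated samples only) + Gaussian noise; counts are rounded to integers.
    With ``log2_effect = 0`` the matrix is a global null.
    """
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(params.n_genes)]
    baseline = rng.normal(
        params.baseline_log2_mean, params.baseline_log2_sd, size=params.n_genes
    )
    de_genes = sorted(
        rng.choice(params.n_genes, size=params.n_de_genes, replace=False)
    )
    effect = np.zeros(params.n_genes)
    effect[de_genes] = params.log2_effect
    lengths = pd.Series(
        rng.integers(500, 5001, size=params.n_genes).astype(float), index=genes
    )

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    group_a, group_b = params.groups
    for day, ramp in zip(params.days, params.ramp):
        for group in (group_a, group_b):
            shift = effect * ramp if group == group_b else 0.0
            for rep in range(params.samples_per_group):
                name = f"{group}_d{day}_r{rep + 1}"
                log2_counts = baseline + shift + rng.normal(
                    0.0, params.noise_sd, size=params.n_genes
                )
                columns[name] = np.rint(2.0**log2_counts).astype(np.int64)
                sheet_rows.append({"sample": name, "group": group, "day": day})

    counts = pd.DataFrame(columns, index=genes)
    sheet = pd.DataFrame(sheet_rows)
    return SyntheticExpression(
        params=params,
        counts=counts,
        sample_sheet=sheet,
        effective_lengths=lengths,
        de_genes=[genes[i] for i in de_genes],
    )
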