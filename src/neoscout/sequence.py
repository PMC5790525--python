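"""Domain types and parsing for proteins, coding sequences, and missense variants.

The unit of analysis is a somatic nonsynonymous single-nucleotide variant
(nsSNV): a single amino-acid substitution in a tumor protein, written in the
community ``P315L`` notation (reference residue, 1-based protein position,
alternate residue).  This module owns

* the 20-letter amino-acid alphabet and its validation,
* FASTA input for proteomes and coding sequences (via Biopython),
* codon translation and application of a missense change to a protein,
* the tabular (TSV) and minimal VCF variant readers.

Coordinates are 1-based and inclusive throughout, matching the notation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
_DNA_SET = frozenset("ACGT")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP = dict(_STANDARD_TABLE.forward_table)
_STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

_MISSENSE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class SequenceError(ValueError):
    """Raised for malformed sequences, notations, or variant tables."""


@dataclass(frozen=True)
class MissenseChange:
    """A single amino-acid substitution in protein coordinates.

    Attributes
    ----------
    ref_aa : str
        Reference residue (one letter).
    position : int
        1-based protein position of the substitution.
    alt_aa : str
        Alternate residue (one letter), distinct from ``ref_aa``.
    """

    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa not in _AA_SET or self.alt_aa not in _AA_SET:
            raise SequenceError(
                f"residues must be in the 20-letter alphabet: "
                f"{self.ref_aa!r}/{self.alt_aa!r}"
            )
        if self.position < 1:
            raise SequenceError(f"protein position must be >= 1, got {self.position}")
        if self.ref_aa == self.alt_aa:
            raise SequenceError(
                f"synonymous change {self.ref_aa}{self.position}{self.alt_aa} "
                "is not a missense variant"
            )

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    def reverse(self) -> "MissenseChange":
        """The change that undoes this one (alt and ref swapped)."""
        return MissenseChange(self.alt_aa, self.position, self.ref_aa)


@dataclass(frozen=True)
class ProteinRecord:
    """A translated gene product: id (transcript), gene symbol, residues."""

    id: str
    gene: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"protein {self.id}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise SequenceError(
                f"protein {self.id}: residues outside 20-letter alphabet: {sorted(bad)}"
            )


@dataclass(frozen=True)
class CdsRecord:
    """A coding DNA sequence tied to a transcript; must translate cleanly."""

    transcript_id: str
    gene: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) % 3 != 0:
            raise SequenceError(
                f"CDS {self.transcript_id}: length {len(self.sequence)} "
                "not divisible by 3"
            )
        bad = set(self.sequence) - _DNA_SET
        if bad:
            raise SequenceError(
                f"CDS {self.transcript_id}: non-ACGT characters {sorted(bad)}"
            )

    def translate(self) -> str:
        try:
            return translate_cds(self.sequence)
        except SequenceError as exc:
            raise SequenceError(f"CDS {self.transcript_id}: {exc}") from exc


@dataclass
class SomaticVariant:
    """One somatic missense variant tied to a gene/transcript.

    ``expressed`` is optional prior evidence (e.g. a targeted-PCR/Sanger
    screen); ``None`` means no evidence either way.  Genomic coordinates
    are optional and only used for Manhattan-plot layout.
    """

    gene: str
    transcript_id: str
    change: MissenseChange
    chrom: Optional[str] = None
    genomic_pos: Optional[int] = None
    expressed: Optional[bool] = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.transcript_id, str(self.change))

    def validate_against(self, protein: ProteinRecord) -> None:
        """Check that ref_aa matches the protein at the stated position."""
        pos = self.change.position
        if pos > len(protein.sequence):
            raise SequenceError(
                f"{self.gene} {self.change}: position {pos} beyond protein "
                f"length {len(protein.sequence)}"
            )
        observed = protein.sequence[pos - 1]
        if observed != self.change.ref_aa:
            raise SequenceError(
                f"{self.gene} {self.change}: reference mismatch, expected "
                f"{self.change.ref_aa} but protein {protein.id} has {observed} "
                f"at position {pos}"
            )


def parse_missense_notation(token: str) -> MissenseChange:
    """Parse ``P315L``-style notation into a :class:`MissenseChange`.

    Raises :class:`SequenceError` naming the token when it is malformed
    (missing alternate residue, position 0, residues outside the alphabet).
    """
    m = _MISSENSE_RE.match(token.strip())
    if not m:
        raise SequenceError(f"malformed missense notation: {token!r}")
    ref, pos_s, alt = m.groups()
    pos = int(pos_s)
    if pos < 1:
        raise SequenceError(f"malformed missense notation (position 0): {token!r}")
    try:
        return MissenseChange(ref, pos, alt)
    except SequenceError as exc:
        raise SequenceError(f"invalid missense notation {token!r}: {exc}") from exc


def translate_cds(cds: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    A terminal stop codon is dropped; an internal stop codon is an error,
    as are non-ACGT characters or a length not divisible by 3.
    """
    if len(cds) % 3 != 0:
        raise SequenceError(f"CDS length {len(cds)} not divisible by 3")
    bad = set(cds) - _DNA_SET
    if bad:
        raise SequenceError(f"non-ACGT characters in CDS: {sorted(bad)}")
    residues = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in _STOP_CODONS:
            if i == n_codons - 1:
                break
            raise SequenceError(f"internal stop codon {codon} at codon {i + 1}")
        residues.append(_CODON_MAP[codon])
    return "".join(residues)


def apply_missense(protein: str, change: MissenseChange) -> str:
    """Apply a missense change to a protein sequence (1-based position).

    The reference residue must match; the result differs from the input at
    exactly one position and has the same length.
    """
    pos = change.position
    if not 1 <= pos <= len(protein):
        raise SequenceError(
            f"position {pos} out of range for protein of length {len(protein)}"
        )
    observed = protein[pos - 1]
    if observed != change.ref_aa:
        raise SequenceError(
            f"reference mismatch at position {pos}: expected {change.ref_aa}, "
            f"observed {observed}"
        )
    return protein[: pos - 1] + change.alt_aa + protein[pos:]


def cds_variant_to_missense(cds: CdsRecord, cds_pos: int, alt_base: str) -> MissenseChange:
    """Lift a CDS-level substitution (1-based base position) to protein level.

    Only missense outcomes are accepted: a synonymous or nonsense
    substitution raises :class:`SequenceError` labelled with its category,
    since only nonsynonymous (amino-acid-changing) variants enter the
    pipeline.
    """
    if alt_base not in _DNA_SET:
        raise SequenceError(f"alternate base must be one of ACGT, got {alt_base!r}")
    if not 1 <= cds_pos <= len(cds.sequence):
        raise SequenceError(
            f"CDS position {cds_pos} out of range for {cds.transcript_id}"
        )
    if cds.sequence[cds_pos - 1] == alt_base:
        raise SequenceError(f"CDS position {cds_pos}: alternate equals reference base")
    codon_idx = (cds_pos - 1) // 3
    within = (cds_pos - 1) % 3
    ref_codon = cds.sequence[3 * codon_idx : 3 * codon_idx + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    if ref_codon in _STOP_CODONS:
        raise SequenceError(f"CDS position {cds_pos} falls in the stop codon")
    ref_aa = _CODON_MAP[ref_codon]
    if alt_codon in _STOP_CODONS:
        raise SequenceError(
            f"nonsense substitution at CDS position {cds_pos} "
            f"({ref_codon}->{alt_codon}); only missense variants are accepted"
        )
    alt_aa = _CODON_MAP[alt_codon]
    if alt_aa == ref_aa:
        raise SequenceError(
            f"synonymous substitution at CDS position {cds_pos} "
            f"({ref_codon}->{alt_codon}); only missense variants are accepted"
        )
    return MissenseChange(ref_aa, codon_idx + 1, alt_aa)


# ---------------------------------------------------------------------------
# File input
# ---------------------------------------------------------------------------

_GENE_RE = re.compile(r"gene=(\S+)")


def _gene_from_description(description: str, default: str) -> str:
    m = _GENE_RE.search(description)
    return m.group(1) if m else default


def read_proteome_fasta(path: str | Path) -> dict[str, ProteinRecord]:
    """Read a proteome FASTA keyed by transcript id.

    The record id is the transcript id; the description may carry
    ``gene=SYMBOL`` (falls back to the id).  A trailing ``*`` (stop) on the
    sequence is stripped before validation.
    """
    records: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).rstrip("*")
        gene = _gene_from_description(rec.description, rec.id)
        if rec.id in records:
            raise SequenceError(f"duplicate FASTA record id {rec.id}")
        records[rec.id] = ProteinRecord(id=rec.id, gene=gene, sequence=seq)
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def read_cds_fasta(path: str | Path) -> dict[str, CdsRecord]:
    """Read a CDS FASTA keyed by transcript id (same header convention)."""
    records: dict[str, CdsRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = _gene_from_description(rec.description, rec.id)
        records[rec.id] = CdsRecord(
            transcript_id=rec.id, gene=gene, sequence=str(rec.seq)
        )
    return records


_REQUIRED_VARIANT_COLUMNS = ("gene", "transcript_id", "protein_change")


def _parse_expressed(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip().lower()
    if s in ("", "na", "nan", "none"):
        return None
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise SequenceError(f"unparsable expressed flag {value!r}")


def read_variant_table(path: str | Path) -> list[SomaticVariant]:
    """Read a somatic-variant TSV into a list of :class:`SomaticVariant`.

    Required columns: gene, transcript_id, protein_change.  Optional:
    chrom, pos (1-based), expressed (true/false/NA).  Malformed rows and
    duplicate (transcript, change) pairs are reported with line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise SequenceError(f"{path}: missing required column(s) {missing}")
    variants: list[SomaticVariant] = []
    seen: dict[tuple[str, str], int] = {}
    duplicates: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            change = parse_missense_notation(str(row["protein_change"]))
        except SequenceError as exc:
            raise SequenceError(f"{path} line {line}: {exc}") from exc
        chrom = row.get("chrom")
        chrom = None if (chrom is None or pd.isna(chrom)) else str(chrom)
        pos = row.get("pos")
        genomic_pos = None if (pos is None or pd.isna(pos)) else int(pos)
        variant = SomaticVariant(
            gene=str(row["gene"]),
            transcript_id=str(row["transcript_id"]),
            change=change,
            chrom=chrom,
            genomic_pos=genomic_pos,
            expressed=_parse_expressed(row.get("expressed")),
        )
        if variant.key in seen:
            duplicates.append(
                f"line {line} duplicates line {seen[variant.key]} "
                f"({variant.transcript_id} {variant.change})"
            )
        else:
            seen[variant.key] = line
            variants.append(variant)
    if duplicates:
        raise SequenceError(f"{path}: duplicate variant rows: " + "; ".join(duplicates))
    return variants


def read_variant_vcf(path: str | Path) -> list[SomaticVariant]:
    """Minimal VCF v4.2 reader for SNV records.

    Requires the custom INFO keys ``TRANSCRIPT`` and ``PCHANGE`` (missense
    notation); ``GENE`` is honoured when present.  Every other field is
    ignored; non-SNV records are rejected.
    """
    variants: list[SomaticVariant] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise SequenceError(f"{path} line {line_no}: too few VCF columns")
            chrom, pos, _id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if len(ref) != 1 or len(alt) != 1:
                raise SequenceError(f"{path} line {line_no}: not an SNV ({ref}>{alt})")
            info = dict(
                kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv
            )
            for key in ("TRANSCRIPT", "PCHANGE"):
                if key not in info:
                    raise SequenceError(
                        f"{path} line {line_no}: missing INFO key {key}"
                    )
            change = parse_missense_notation(info["PCHANGE"])
            variants.append(
                SomaticVariant(
                    gene=info.get("GENE", info["TRANSCRIPT"]),
                    transcript_id=info["TRANSCRIPT"],
                    change=change,
                    chrom=chrom,
                    genomic_pos=int(pos),
                )
            )
    return variants
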