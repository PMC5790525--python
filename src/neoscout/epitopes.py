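"""Mutant peptide window enumeration and synthetic long peptide design.

Given a mutant protein and the position of its altered residue, every
candidate MHC class I epitope is a k-mer window (k per allele, typically
8-11) whose span covers the altered residue.  Each mutant window is paired
with its wild-type counterpart (differing at exactly one residue), which
serves as the specificity control downstream.

The synthetic long peptide (SLP) designer produces an extended vaccine
peptide (default 28-mer) with the mutant residue near the middle, so that
in-vivo processing can liberate the embedded minimal epitope.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequence import SomaticVariant, SequenceError

_VALID_LENGTHS = frozenset({8, 9, 10, 11})


@dataclass(frozen=True)
class MhcAllele:
    """An MHC class I allele and the peptide lengths its groove accepts."""

    name: str
    peptide_lengths: frozenset[int]

    def __post_init__(self) -> None:
        lengths = frozenset(self.peptide_lengths)
        object.__setattr__(self, "peptide_lengths", lengths)
        if not lengths:
            raise ValueError(f"allele {self.name}: no peptide lengths")
        if not lengths <= _VALID_LENGTHS:
            raise ValueError(
                f"allele {self.name}: lengths must be within {sorted(_VALID_LENGTHS)}"
            )


# Canonical groove preferences for the two C57BL/6 class I alleles.
H2_KB = MhcAllele("H-2Kb", frozenset({8, 9}))
H2_DB = MhcAllele("H-2Db", frozenset({9, 10}))
DEFAULT_ALLELES = (H2_KB, H2_DB)


@dataclass(frozen=True)
class PeptideCandidate:
    """A mutant k-mer window paired with its wild-type counterpart.

    ``window_start`` is the 1-based protein coordinate of the first residue;
    ``mut_offset`` is the 1-based position of the altered residue within the
    window.
    """

    variant: SomaticVariant
    allele: MhcAllele
    mutant_peptide: str
    wildtype_peptide: str
    window_start: int
    mut_offset: int

    def __post_init__(self) -> None:
        k = len(self.mutant_peptide)
        if k not in self.allele.peptide_lengths:
            raise ValueError(
                f"window length {k} not allowed for allele {self.allele.name}"
            )
        if len(self.wildtype_peptide) != k:
            raise ValueError("mutant and wild-type windows differ in length")
        if not 1 <= self.mut_offset <= k:
            raise ValueError(f"mut_offset {self.mut_offset} outside window")
        diffs = [
            i + 1
            for i, (a, b) in enumerate(zip(self.mutant_peptide, self.wildtype_peptide))
            if a != b
        ]
        if diffs != [self.mut_offset]:
            raise ValueError(
                f"mutant/wild-type pair must differ exactly at offset "
                f"{self.mut_offset}, differs at {diffs}"
            )
        if self.mutant_peptide[self.mut_offset - 1] != self.variant.change.alt_aa:
            raise ValueError("altered residue does not match the variant's alt_aa")

    @property
    def id(self) -> str:
        """Stable candidate id used to trace report rows back to variants."""
        return (
            f"{self.variant.gene}_{self.variant.change}_{self.allele.name}"
            f"_L{len(self.mutant_peptide)}_s{self.window_start}"
        )


@dataclass(frozen=True)
class LongPeptide:
    """A vaccine long peptide containing the mutant residue."""

    sequence: str
    total_len: int
    mut_offset: int

    def __post_init__(self) -> None:
        if not 1 <= self.mut_offset <= len(self.sequence):
            raise ValueError("mut_offset outside long peptide")
        if len(self.sequence) > self.total_len:
            raise ValueError("long peptide exceeds requested length")


def enumerate_mutant_windows(
    mut_protein: str,
    wt_protein: str,
    position: int,
    allele: MhcAllele,
    variant: SomaticVariant,
) -> list[PeptideCandidate]:
    """Enumerate all allele-length windows covering the altered residue.

    For each k in the allele's accepted lengths, every k-mer of the mutant
    protein whose span contains ``position`` (1-based) and lies fully within
    the protein is returned, paired with the wild-type window at the same
    coordinates.  Proteins shorter than k simply contribute no windows of
    that length.
    """
    n = len(mut_protein)
    if len(wt_protein) != n:
        raise SequenceError("mutant and wild-type proteins differ in length")
    if not 1 <= position <= n:
        raise SequenceError(f"position {position} out of range for length {n}")
    candidates: list[PeptideCandidate] = []
    seen: set[tuple[str, str, int]] = set()
    for k in sorted(allele.peptide_lengths):
        lo = max(1, position - k + 1)
        hi = min(position, n - k + 1)
        for start in range(lo, hi + 1):
            mut = mut_protein[start - 1 : start - 1 + k]
            wt = wt_protein[start - 1 : start - 1 + k]
            key = (allele.name, mut, start)
            if key in seen:
                continue
            seen.add(key)
            candidates.append(
                PeptideCandidate(
                    variant=variant,
                    allele=allele,
                    mutant_peptide=mut,
                    wildtype_peptide=wt,
                    window_start=start,
                    mut_offset=position - start + 1,
                )
            )
    return candidates


def design_long_peptide(
    mut_protein: str, position: int, total_len: int = 28
) -> LongPeptide:
    """Design a synthetic long peptide around the mutant residue.

    The mutant residue is placed at offset ceil(total_len / 2); the window
    shifts (and may shorten) only when a protein terminus forces truncation.
    """
    n = len(mut_protein)
    if not 1 <= position <= n:
        raise SequenceError(f"position {position} out of range for length {n}")
    if total_len < 1:
        raise ValueError("total_len must be >= 1")
    target_offset = (total_len + 1) // 2
    start = position - target_offset + 1
    end = start + total_len - 1
    if start < 1:
        start = 1
        end = min(n, total_len)
    elif end > n:
        end = n
        start = max(1, n - total_len + 1)
    seq = mut_protein[start - 1 : end]
    return LongPeptide(sequence=seq, total_len=total_len, mut_offset=position - start + 1)


def wildtype_pair(candidate: PeptideCandidate) -> str:
    """Return the wild-type counterpart (Hamming distance exactly 1)."""
    return candidate.wildtype_peptide
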