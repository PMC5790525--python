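"""Ranking and tiering of scored neoantigen candidates.

Candidates are ranked by ascending consensus IC50 and reported with the
affinity score (1/IC50) x 100, so stronger predicted binders get larger
scores.  Tier membership uses strict thresholds (IC50 < 500, < 50, < 25 nM),
nested by construction.  ``manhattan_table`` lays candidates out along a
cumulative genomic axis for Manhattan-style plots, falling back to the
candidate index when genomic coordinates are absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pandas as pd

from .binding import ConsensusResult

logger = logging.getLogger(__name__)

DEFAULT_TIERS_NM = (500.0, 50.0, 25.0)

_TIER_NAMES = {500.0: "lt500", 50.0: "lt50", 25.0: "lt25"}


@dataclass(frozen=True)
class NeoantigenCandidate:
    """A prioritized, expression-annotated candidate row."""

    consensus: ConsensusResult
    affinity_score: float
    tier: str
    expressed: Optional[bool] = None
    rank: int = 0

    @property
    def ic50(self) -> float:
        return self.consensus.consensus_ic50_nM

    @property
    def gene(self) -> str:
        return self.consensus.candidate.variant.gene

    @property
    def peptide(self) -> str:
        return self.consensus.candidate.mutant_peptide


def affinity_score(ic50_nM: float) -> float:
    """The ranking score (1/IC50) x 100; strictly decreasing in IC50."""
    if ic50_nM <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return 100.0 / ic50_nM


def assign_tier(ic50_nM: float, tiers: Sequence[float] = DEFAULT_TIERS_NM) -> str:
    """Name of the strictest tier the IC50 falls under ('none' if it misses all)."""
    best = "none"
    for threshold in sorted(tiers, reverse=True):
        if ic50_nM < threshold:
            best = _TIER_NAMES.get(threshold, f"lt{threshold:g}")
    return best


def make_candidate(
    consensus: ConsensusResult,
    expressed: Optional[bool] = None,
    tiers: Sequence[float] = DEFAULT_TIERS_NM,
) -> NeoantigenCandidate:
    ic50 = consensus.consensus_ic50_nM
    return NeoantigenCandidate(
        consensus=consensus,
        affinity_score=affinity_score(ic50),
        tier=assign_tier(ic50, tiers),
        expressed=expressed,
    )


def tier_filter(
    candidates: Sequence[NeoantigenCandidate], threshold_nM: float
) -> list[NeoantigenCandidate]:
    """Candidates with consensus IC50 strictly below the threshold."""
    if threshold_nM <= 0:
        raise ValueError("threshold must be positive")
    return [c for c in candidates if c.ic50 < threshold_nM]


def rank_candidates(
    candidates: Sequence[NeoantigenCandidate],
) -> list[NeoantigenCandidate]:
    """Sort ascending by IC50, ties by gene symbol then peptide; assign ranks."""
    ordered = sorted(candidates, key=lambda c: (c.ic50, c.gene, c.peptide))
    return [replace(c, rank=i + 1) for i, c in enumerate(ordered)]


def candidates_to_frame(candidates: Sequence[NeoantigenCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        pc = c.consensus.candidate
        v = pc.variant
        rows.append(
            {
                "rank": c.rank,
                "candidate_id": pc.id,
                "gene": v.gene,
                "transcript_id": v.transcript_id,
                "protein_change": str(v.change),
                "allele": pc.allele.name,
                "length": len(pc.mutant_peptide),
                "window_start": pc.window_start,
                "mut_offset": pc.mut_offset,
                "mutant_peptide": pc.mutant_peptide,
                "wildtype_peptide": pc.wildtype_peptide,
                "consensus_ic50_nM": c.ic50,
                "affinity_score": c.affinity_score,
                "tier": c.tier,
                "expressed": c.expressed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank",
            "candidate_id",
            "gene",
            "transcript_id",
            "protein_change",
            "allele",
            "length",
            "window_start",
            "mut_offset",
            "mutant_peptide",
            "wildtype_peptide",
            "consensus_ic50_nM",
            "affinity_score",
            "tier",
            "expressed",
        ],
    )


def manhattan_table(candidates: Sequence[NeoantigenCandidate]) -> pd.DataFrame:
    """Plot-data rows: x (cumulative genomic coordinate or index), y, label.

    Genomic layout requires every candidate to carry chrom/pos; mixed
    presence falls back to index mode with a warning.  Ordering is
    deterministic: genomic (chrom, pos) when available, else input order.
    """
    variants = [c.consensus.candidate.variant for c in candidates]
    have_coords = [v.chrom is not None and v.genomic_pos is not None for v in variants]
    use_genomic = bool(candidates) and all(have_coords)
    if any(have_coords) and not use_genomic:
        logger.warning(
            "mixed presence of genomic coordinates; falling back to index layout"
        )
    rows = []
    if use_genomic:
        order = sorted(
            range(len(candidates)),
            key=lambda i: (str(variants[i].chrom), variants[i].genomic_pos),
        )
        # cumulative offset per chromosome, chromosomes in sorted-name order
        chrom_max: dict[str, int] = {}
        for v in variants:
            chrom_max[str(v.chrom)] = max(
                chrom_max.get(str(v.chrom), 0), int(v.genomic_pos)
            )
        offset = 0
        chrom_offset: dict[str, int] = {}
        for chrom in sorted(chrom_max):
            chrom_offset[chrom] = offset
            offset += chrom_max[chrom]
        for i in order:
            c, v = candidates[i], variants[i]
            rows.append(
                {
                    "x": chrom_offset[str(v.chrom)] + int(v.genomic_pos),
                    "y": c.affinity_score,
                    "chrom": str(v.chrom),
                    "pos": int(v.genomic_pos),
                    "label": f"{v.gene}_{v.change}",
                }
            )
    else:
        for i, c in enumerate(candidates):
            v = variants[i]
            rows.append(
                {
                    "x": i + 1,
                    "y": c.affinity_score,
                    "chrom": None,
                    "pos": None,
                    "label": f"{v.gene}_{v.change}",
                }
            )
    return pd.DataFrame(rows, columns=["x", "y", "chrom", "pos", "label"])
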