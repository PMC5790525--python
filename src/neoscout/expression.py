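"""Expression evidence screen: drop candidates whose transcript is silent.

Mirrors the study design where high-affinity candidates were screened for
transcript expression before validation: a boolean per-transcript evidence
flag (the stand-in for a targeted PCR/Sanger confirmation) takes precedence;
otherwise a TPM threshold (default 1.0) decides.  Candidates are annotated
rather than silently dropped — rejects are returned alongside survivors so
the two partitions always reconstruct the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .prioritize import NeoantigenCandidate


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionTable:
    """Per-transcript TPM plus optional boolean evidence overrides."""

    tpm: dict[str, float] = field(default_factory=dict)
    evidence: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tx, value in self.tpm.items():
            if value < 0:
                raise ExpressionError(f"negative TPM for {tx}: {value}")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
        for col in ("transcript_id", "tpm"):
            if col not in df.columns:
                raise ExpressionError(f"{path}: missing column {col}")
        tpm = dict(zip(df["transcript_id"], df["tpm"].astype(float)))
        evidence: dict[str, bool] = {}
        if "evidence" in df.columns:
            for tx, ev in zip(df["transcript_id"], df["evidence"]):
                if pd.isna(ev) or str(ev).strip().lower() in ("", "na", "none"):
                    continue
                evidence[tx] = str(ev).strip().lower() in ("true", "1", "yes")
        return cls(tpm=tpm, evidence=evidence)

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "transcript_id": tx,
                "tpm": tpm,
                "evidence": self.evidence.get(tx, "NA"),
            }
            for tx, tpm in self.tpm.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def is_expressed(
        self, transcript_id: str, min_tpm: float, missing: str = "strict"
    ) -> bool:
        if transcript_id in self.evidence:
            return self.evidence[transcript_id]
        if transcript_id not in self.tpm:
            if missing == "strict":
                raise ExpressionError(
                    f"transcript {transcript_id} absent from expression table"
                )
            return False
        return self.tpm[transcript_id] >= min_tpm


def filter_expressed(
    candidates: Sequence[NeoantigenCandidate],
    table: ExpressionTable,
    min_tpm: float = 1.0,
    missing: str = "strict",
) -> tuple[list[NeoantigenCandidate], list[NeoantigenCandidate]]:
    """Partition candidates into (survivors, rejects) by expression.

    A candidate survives when its transcript has evidence == True, or no
    evidence and TPM >= min_tpm.  ``missing='strict'`` (default) raises on
    transcripts absent from the table; ``'lenient'`` marks them unexpressed.
    Both partitions come back with the ``expressed`` field annotated.
    """
    if missing not in ("strict", "lenient"):
        raise ValueError(f"unknown missing-transcript policy {missing!r}")
    survivors: list[NeoantigenCandidate] = []
    rejects: list[NeoantigenCandidate] = []
    for cand in candidates:
        tx = cand.consensus.candidate.variant.transcript_id
        ok = table.is_expressed(tx, min_tpm=min_tpm, missing=missing)
        annotated = replace(cand, expressed=ok)
        (survivors if ok else rejects).append(annotated)
    return survivors, rejects
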