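"""Run configuration: input paths, thresholds, allele length map, seed.

A run is described by a single declarative YAML (or dict) with CLI
overrides layered on top.  Tier thresholds must be positive and strictly
decreasing; referenced files must exist at validation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .epitopes import MhcAllele, DEFAULT_ALLELES


class ConfigValidationError(ValueError):
    pass


@dataclass
class RunConfig:
    proteome: Optional[str] = None
    variants: Optional[str] = None
    matrix_dir: Optional[str] = None
    expression: Optional[str] = None
    counts: Optional[str] = None
    sample_sheet: Optional[str] = None
    lengths: Optional[str] = None
    outdir: str = "neoscout_out"
    seed: int = 0
    tiers_nM: tuple = (500.0, 50.0, 25.0)
    min_tpm: float = 1.0
    q_cutoff: float = 0.05
    consensus_scale: str = "log"
    missing_expression: str = "strict"
    allele_lengths: dict = field(
        default_factory=lambda: {a.name: sorted(a.peptide_lengths) for a in DEFAULT_ALLELES}
    )

    def __post_init__(self) -> None:
        tiers = tuple(float(t) for t in self.tiers_nM)
        if any(t <= 0 for t in tiers):
            raise ConfigValidationError("tier thresholds must be positive")
        if list(tiers) != sorted(tiers, reverse=True):
            raise ConfigValidationError(
                "tier thresholds must be strictly decreasing"
            )
        if len(set(tiers)) != len(tiers):
            raise ConfigValidationError("tier thresholds must be distinct")
        self.tiers_nM = tiers

    @property
    def alleles(self) -> tuple[MhcAllele, ...]:
        return tuple(
            MhcAllele(name, frozenset(int(k) for k in ks))
            for name, ks in sorted(self.allele_lengths.items())
        )

    def require(self, *keys: str) -> None:
        """Check that the named inputs are set and exist on disk."""
        for key in keys:
            value = getattr(self, key)
            if value is None:
                raise ConfigValidationError(f"config is missing required input {key!r}")
            if not Path(value).exists():
                raise ConfigValidationError(f"{key} path does not exist: {value}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tiers_nM"] = list(self.tiers_nM)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigValidationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)
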