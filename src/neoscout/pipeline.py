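"""End-to-end pipeline wiring: discover, de, simulate.

Each entry point reads its inputs through the module readers, runs the
stages in order, writes the report bundle into the configured output
directory, and records a manifest (config echo + seed + per-stage record
counts).  Stage failures are wrapped in :class:`StageError` naming the
stage, so the CLI can map them to exit codes.  Outputs are deterministic:
rerunning on identical inputs reproduces identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .binding import PredictorRegistry
from .config import RunConfig, ConfigValidationError
from .de import (
    SampleSheet,
    compute_tpm,
    differential_expression,
    temporal_profile,
    volcano_table,
)
from .epitopes import enumerate_mutant_windows
from .expression import ExpressionTable, filter_expressed
from .prioritize import (
    candidates_to_frame,
    make_candidate,
    manhattan_table,
    rank_candidates,
    tier_filter,
)
from .sequence import apply_missense, read_proteome_fasta, read_variant_table
from .simulate import SimulationConfig, simulate_cohort, simulate_expression

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _write_manifest(outdir: Path, command: str, config: RunConfig, counts: dict) -> Path:
    manifest = {
        "command": command,
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stage_counts": counts,
    }
    path = outdir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_discover(config: RunConfig) -> dict[str, Path]:
    """Variants -> windows -> consensus IC50 -> expression filter -> report."""
    try:
        config.require("proteome", "variants", "matrix_dir", "expression")
    except ConfigValidationError:
        raise
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    try:
        proteins = read_proteome_fasta(config.proteome)
        variants = read_variant_table(config.variants)
        for v in variants:
            if v.transcript_id not in proteins:
                raise ValueError(f"variant transcript {v.transcript_id} not in proteome")
            v.validate_against(proteins[v.transcript_id])
    except Exception as exc:
        raise StageError("sequence_model", str(exc)) from exc
    counts["variants"] = len(variants)
    logger.info("loaded %d validated missense variants", len(variants))

    try:
        matrix_paths = sorted(Path(config.matrix_dir).glob("*.tsv"))
        registry = PredictorRegistry.from_paths(matrix_paths)
        if not registry.predictor_ids:
            raise ValueError(f"no matrix files found under {config.matrix_dir}")
    except Exception as exc:
        raise StageError("binding_prediction", str(exc)) from exc

    try:
        candidates = []
        alleles = config.alleles
        for v in variants:
            wt = proteins[v.transcript_id].sequence
            mut = apply_missense(wt, v.change)
            for allele in alleles:
                candidates.extend(
                    enumerate_mutant_windows(mut, wt, v.change.position, allele, v)
                )
    except Exception as exc:
        raise StageError("epitope_enumeration", str(exc)) from exc
    counts["windows"] = len(candidates)
    logger.info("enumerated %d mutant peptide windows", len(candidates))

    try:
        scored = [
            make_candidate(
                registry.predict_candidate(pc, scale=config.consensus_scale),
                tiers=config.tiers_nM,
            )
            for pc in candidates
        ]
    except Exception as exc:
        raise StageError("binding_prediction", str(exc)) from exc
    counts["scored"] = len(scored)

    try:
        table = ExpressionTable.read_tsv(config.expression)
        survivors, rejects = filter_expressed(
            scored, table, min_tpm=config.min_tpm, missing=config.missing_expression
        )
    except Exception as exc:
        raise StageError("expression_evidence", str(exc)) from exc
    counts["expressed"] = len(survivors)
    logger.info(
        "expression screen kept %d / %d candidates", len(survivors), len(scored)
    )

    ranked = rank_candidates(survivors)
    paths: dict[str, Path] = {}
    paths["report"] = outdir / "report_ranked.tsv"
    candidates_to_frame(ranked).to_csv(
        paths["report"], sep="\t", index=False, float_format=_FLOAT_FMT
    )
    for threshold in config.tiers_nM:
        subset = rank_candidates(tier_filter(ranked, threshold))
        key = f"tier_lt{threshold:g}"
        counts[key] = len(subset)
        paths[key] = outdir / f"candidates_lt{threshold:g}nM.tsv"
        candidates_to_frame(subset).to_csv(
            paths[key], sep="\t", index=False, float_format=_FLOAT_FMT
        )
        logger.info("%d candidates below %g nM", len(subset), threshold)
    paths["rejects"] = outdir / "rejects.tsv"
    candidates_to_frame(rank_candidates(rejects)).to_csv(
        paths["rejects"], sep="\t", index=False, float_format=_FLOAT_FMT
    )
    paths["manhattan"] = outdir / "manhattan.tsv"
    manhattan_table(ranked).to_csv(
        paths["manhattan"], sep="\t", index=False, float_format=_FLOAT_FMT
    )
    paths["manifest"] = _write_manifest(outdir, "discover", config, counts)
    return paths


def run_de(config: RunConfig) -> dict[str, Path]:
    """Counts -> TPM -> per-day t-tests with BH -> volcano/temporal tables."""
    config.require("counts", "sample_sheet", "lengths")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_meta: dict[str, int] = {}

    try:
        counts = pd.read_csv(config.counts, sep="\t", index_col="gene")
        sheet = SampleSheet.read_tsv(config.sample_sheet)
        lengths = pd.read_csv(config.lengths, sep="\t", index_col="gene")[
            "effective_length"
        ]
        if counts.shape[0] == 0:
            raise ValueError("empty gene set")
        tpm = compute_tpm(counts, lengths)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("transcriptome_de", str(exc)) from exc

    groups = sheet.groups
    if len(groups) != 2:
        raise StageError(
            "transcriptome_de", f"expected exactly 2 groups, got {groups}"
        )
    group_a, group_b = groups[0], groups[1]
    # convention: 'control'-like group is the baseline when present
    if "control" in groups and group_a != "control":
        group_a, group_b = group_b, group_a
    days = sheet.days
    paths: dict[str, Path] = {}

    try:
        focus_day = days[-1] if days else None
        de = differential_expression(tpm, sheet, group_a, group_b, day=focus_day)
    except Exception as exc:
        raise StageError("transcriptome_de", str(exc)) from exc
    counts_meta["genes_tested"] = len(de)
    counts_meta["significant_q"] = int((de["q_value"] < config.q_cutoff).sum())
    logger.info(
        "DE (%s vs %s%s): %d genes, %d at q < %g",
        group_b,
        group_a,
        f", day {focus_day}" if focus_day is not None else "",
        len(de),
        counts_meta["significant_q"],
        config.q_cutoff,
    )
    paths["de"] = outdir / "de_results.tsv"
    de.to_csv(paths["de"], sep="\t", index_label="gene", float_format=_FLOAT_FMT)
    paths["volcano"] = outdir / "volcano.tsv"
    volcano_table(de, q_cutoff=config.q_cutoff).to_csv(
        paths["volcano"], sep="\t", index=False, float_format=_FLOAT_FMT
    )
    if len(days) > 1:
        tpm_by_day = {
            day: tpm[[s for s in tpm.columns if s in set(sheet.samples(group_a, day)) | set(sheet.samples(group_b, day))]]
            for day in days
        }
        temporal = temporal_profile(tpm_by_day, sheet, group_a, group_b)
        paths["temporal"] = outdir / "temporal.tsv"
        temporal.to_csv(
            paths["temporal"], sep="\t", index_label="gene", float_format=_FLOAT_FMT
        )
    paths["manifest"] = _write_manifest(outdir, "de", config, counts_meta)
    return paths


def run_simulate(
    config: RunConfig, sim_config: Optional[SimulationConfig] = None
) -> dict[str, Path]:
    """Generate the full synthetic input bundle into the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if sim_config is None:
        sim_config = SimulationConfig(seed=config.seed)
    cohort = simulate_cohort(sim_config)
    paths = cohort.write(outdir)
    expr = simulate_expression(sim_config.de_params, seed=config.seed)
    paths.update(expr.write(outdir / "rnaseq"))
    counts = {
        "proteins": len(cohort.proteins),
        "variants": len(cohort.variants),
        "matrices": len(cohort.matrices),
        "rnaseq_genes": sim_config.de_params.n_genes,
    }
    paths["manifest"] = _write_manifest(outdir, "simulate", config, counts)
    return paths


def discover_config_for(bundle_dir: str | Path, seed: int = 0, **overrides) -> RunConfig:
    """Convenience RunConfig pointing at a ``run_simulate`` output bundle."""
    bundle_dir = Path(bundle_dir)
    defaults = dict(
        proteome=str(bundle_dir / "proteome.fasta"),
        variants=str(bundle_dir / "variants.tsv"),
        matrix_dir=str(bundle_dir / "matrices"),
        expression=str(bundle_dir / "expression.tsv"),
        counts=str(bundle_dir / "rnaseq" / "counts.tsv"),
        sample_sheet=str(bundle_dir / "rnaseq" / "samples.tsv"),
        lengths=str(bundle_dir / "rnaseq" / "lengths.tsv"),
        outdir=str(bundle_dir / "results"),
        seed=seed,
    )
    defaults.update(overrides)
    return RunConfig(**defaults)
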