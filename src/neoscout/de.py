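"""Bulk RNA-Seq differential expression: TPM, t-tests, BH correction.

The statistics mirror a standard sorted-population RNA-Seq workflow:
transcript abundance is expressed in TPM (length-normalised rates scaled to
sum to one million per sample), group differences are tested per gene with a
two-sample t-test on log2(TPM + 1), and p-values are adjusted with the
Benjamini-Hochberg step-up procedure.  The classical pooled-variance
(Student) t-test is the default — with equal group sizes and a common
within-group variance it is exactly calibrated even at n = 3 — and the
Welch unequal-variance test is available via ``equal_var=False``.

Degenerate genes (zero variance in both groups, equal means) get t = 0,
p = 1 rather than being dropped, so the number of tests entering BH is
always the number of genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SIGNIFICANCE_Q = 0.05


class DEError(ValueError):
    pass


@dataclass
class SampleSheet:
    """Sample annotations: group label and (optional) day per sample."""

    frame: pd.DataFrame  # columns: sample, group, day

    def __post_init__(self) -> None:
        for col in ("sample", "group"):
            if col not in self.frame.columns:
                raise DEError(f"sample sheet missing column {col}")
        if self.frame["sample"].duplicated().any():
            raise DEError("duplicate sample names in sample sheet")

    @classmethod
    def read_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str}))

    def samples(self, group: str, day=None) -> list[str]:
        df = self.frame
        mask = df["group"] == group
        if day is not None:
            mask &= df["day"] == day
        return list(df.loc[mask, "sample"])

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    @property
    def days(self) -> list:
        if "day" not in self.frame.columns:
            return []
        return sorted(self.frame["day"].dropna().unique())


def compute_tpm(counts: pd.DataFrame, effective_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from read counts and effective lengths.

    tpm_g = (c_g / l_g) / sum_j (c_j / l_j) * 1e6, per sample; every sample
    column sums to one million.  An all-zero sample is an error naming the
    sample.
    """
    lengths = effective_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise DEError(f"effective length missing for genes {missing}")
    if (lengths <= 0).any():
        raise DEError("effective lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise DEError("counts must be non-negative")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise DEError(f"all-zero sample(s): {list(zero.index)}")
    return rates.div(totals, axis=1) * 1e6


def log_transform(tpm: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM + 1); the pseudocount keeps zero-TPM genes finite."""
    return np.log2(tpm + 1.0)


def de_test(
    log_expr_a: pd.DataFrame,
    log_expr_b: pd.DataFrame,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene two-sample t-test on log2 expression (B minus A).

    Returns a frame with log2fc, t_stat, p_value indexed by gene.  Both
    frames must share a gene index and have >= 2 samples.  Genes constant
    and equal in both groups get t = 0, p = 1; constant but unequal groups
    get an infinite t and p = 0.
    """
    if not log_expr_a.index.equals(log_expr_b.index):
        raise DEError("gene indexes differ between groups")
    if log_expr_a.shape[1] < 2 or log_expr_b.shape[1] < 2:
        raise DEError("each group needs at least 2 samples")
    a = log_expr_a.to_numpy(dtype=float)
    b = log_expr_b.to_numpy(dtype=float)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p_value = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
        log2fc = b.mean(axis=1) - a.mean(axis=1)
        degenerate = ~np.isfinite(t_stat)
        if degenerate.any():
            equal_means = np.isclose(log2fc, 0.0)
            t_stat = np.where(degenerate & equal_means, 0.0, t_stat)
            p_value = np.where(degenerate & equal_means, 1.0, p_value)
            unequal = degenerate & ~equal_means
            t_stat = np.where(unequal, np.sign(log2fc) * np.inf, t_stat)
            p_value = np.where(unequal, 0.0, p_value)
    return pd.DataFrame(
        {"log2fc": log2fc, "t_stat": t_stat, "p_value": p_value},
        index=log_expr_a.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DEError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def differential_expression(
    tpm: pd.DataFrame,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    day=None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """End-to-end DE table: log2fc, t, p, BH q per gene (B vs A)."""
    samples_a = sheet.samples(group_a, day)
    samples_b = sheet.samples(group_b, day)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise DEError(
            f"groups need >= 2 samples (got {len(samples_a)} {group_a}, "
            f"{len(samples_b)} {group_b}"
            + (f" at day {day}" if day is not None else "")
            + ")"
        )
    log_expr = log_transform(tpm)
    result = de_test(log_expr[samples_a], log_expr[samples_b], equal_var=equal_var)
    result["q_value"] = bh_adjust(result["p_value"].to_numpy())
    return result


def temporal_profile(
    tpm_by_day: dict,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    genes=None,
) -> pd.DataFrame:
    """Per-gene induction across days: group means, difference, monotonicity.

    ``tpm_by_day`` maps day label -> TPM frame containing that day's
    samples.  Returns one row per gene with per-day mean log2(TPM+1) for
    each group, the B-minus-A difference per day, whether the difference
    increases monotonically across days, and the day of maximal difference.
    """
    days = sorted(tpm_by_day)
    if not days:
        raise DEError("no days provided")
    frames = {}
    for day in days:
        tpm = tpm_by_day[day]
        sa = [s for s in sheet.samples(group_a, day) if s in tpm.columns]
        sb = [s for s in sheet.samples(group_b, day) if s in tpm.columns]
        if not sa or not sb:
            raise DEError(f"day {day}: both groups must have samples")
        log_expr = log_transform(tpm)
        frames[day] = (
            log_expr[sa].mean(axis=1),
            log_expr[sb].mean(axis=1),
        )
    index = frames[days[0]][0].index
    if genes is not None:
        index = index.intersection(pd.Index(genes))
    out = pd.DataFrame(index=index)
    diffs = []
    for day in days:
        mean_a, mean_b = frames[day]
        out[f"mean_{group_a}_d{day}"] = mean_a.loc[index]
        out[f"mean_{group_b}_d{day}"] = mean_b.loc[index]
        diff = (mean_b - mean_a).loc[index]
        out[f"diff_d{day}"] = diff
        diffs.append(diff.to_numpy())
    diff_matrix = np.column_stack(diffs)
    out["is_monotone_increasing"] = np.all(
        np.diff(diff_matrix, axis=1) > 0, axis=1
    )
    out["argmax_day"] = [days[i] for i in np.argmax(diff_matrix, axis=1)]
    return out


def volcano_table(de_results: pd.DataFrame, q_cutoff: float = SIGNIFICANCE_Q) -> pd.DataFrame:
    """Volcano plot rows: x = log2fc, y = -log10(q), significance at q < cutoff."""
    q = de_results["q_value"].to_numpy(dtype=float)
    q_floored = np.maximum(q, np.finfo(float).eps)
    return pd.DataFrame(
        {
            "gene": de_results.index,
            "x": de_results["log2fc"].to_numpy(),
            "y": -np.log10(q_floored),
            "significant": q < q_cutoff,
        }
    )
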