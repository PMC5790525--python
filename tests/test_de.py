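"""TPM computation, t-tests on log expression, BH adjustment, tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neoscout.de import (
    DEError,
    SampleSheet,
    bh_adjust,
    compute_tpm,
    de_test,
    differential_expression,
    temporal_profile,
    volcano_table,
)
from neoscout.simulate import DEParams, simulate_expression


def bh_oracle(p):
    """Brute-force step-up: q_i = min over j with p_(j) >= p_(i) of p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running = min(running, p[i] * m / (rank_from_top + 1))
        q[i] = min(running, 1.0)
    return q


class TestComputeTpm:
    def test_equal_counts_equal_lengths_symmetric(self):
        counts = pd.DataFrame({"s1": [5, 5, 5, 5]}, index=list("abcd"))
        lengths = pd.Series([100.0] * 4, index=list("abcd"))
        tpm = compute_tpm(counts, lengths)
        assert np.allclose(tpm["s1"], 250_000.0)

    def test_length_normalisation(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
        lengths = pd.Series([1.0, 2.0], index=["a", "b"])
        tpm = compute_tpm(counts, lengths)
        assert tpm.loc["a", "s1"] == pytest.approx(666_666.6667, rel=1e-6)
        assert tpm.loc["b", "s1"] == pytest.approx(333_333.3333, rel=1e-6)

    def test_scale_invariance(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(30, 3)), columns=["a", "b", "c"]
        )
        lengths = pd.Series(rng.uniform(200, 2000, 30), index=counts.index)
        tpm1 = compute_tpm(counts, lengths)
        tpm2 = compute_tpm(counts * 2, lengths)
        assert np.allclose(tpm1.to_numpy(), tpm2.to_numpy())

    def test_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 900, size=(100, 4)))
        counts.iloc[0] += 1  # no all-zero sample
        lengths = pd.Series(rng.uniform(300, 4000, 100), index=counts.index)
        sums = compute_tpm(counts, lengths).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-9)

    def test_all_zero_sample_named(self):
        counts = pd.DataFrame({"good": [1, 2], "bad": [0, 0]})
        lengths = pd.Series([100.0, 100.0], index=counts.index)
        with pytest.raises(DEError, match="bad"):
            compute_tpm(counts, lengths)


class TestDeTest:
    def _frames(self, a, b):
        genes = [f"g{i}" for i in range(len(a))]
        return (
            pd.DataFrame(a, index=genes),
            pd.DataFrame(b, index=genes),
        )

    def test_identical_groups_null(self):
        a, b = self._frames([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        res = de_test(a, b)
        assert res.loc["g0", "log2fc"] == 0.0
        assert res.loc["g0", "p_value"] == pytest.approx(1.0)

    def test_textbook_vectors_match_closed_form(self):
        # {1,2,3} vs {4,5,6}: means 2 and 5, s^2 = 1 each
        # t = (5-2)/sqrt(1/3 + 1/3) = 3.674235; Welch df = 4; p = 0.0213116
        a, b = self._frames([[1.0, 2.0, 3.0]], [[4.0, 5.0, 6.0]])
        res = de_test(a, b)
        assert res.loc["g0", "t_stat"] == pytest.approx(3.674234614, rel=1e-9)
        assert res.loc["g0", "p_value"] == pytest.approx(0.0213116, rel=1e-4)
        assert res.loc["g0", "log2fc"] == pytest.approx(3.0)

    def test_label_swap_antisymmetry(self, rng):
        a = pd.DataFrame(rng.normal(5, 1, size=(20, 4)))
        b = pd.DataFrame(rng.normal(5.5, 1, size=(20, 4)))
        fwd = de_test(a, b)
        rev = de_test(b, a)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["t_stat"], -rev["t_stat"])
        assert np.allclose(fwd["p_value"], rev["p_value"])

    def test_constant_equal_gene_p_one(self):
        a, b = self._frames([[2.0, 2.0, 2.0]], [[2.0, 2.0, 2.0]])
        res = de_test(a, b)
        assert res.loc["g0", "t_stat"] == 0.0
        assert res.loc["g0", "p_value"] == 1.0

    def test_single_sample_group_rejected(self):
        a, b = self._frames([[1.0]], [[2.0, 3.0]])
        with pytest.raises(DEError, match="2 samples"):
            de_test(a, b)


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_equally_spaced_collapse(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_all_ones_capped(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(DEError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=200)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_oracle(self, p):
        q = bh_adjust(p)
        assert np.allclose(q, bh_oracle(p))
        assert np.all(q >= np.asarray(p) - 1e-12)  # q_value >= p_value

    def test_large_random_vector_against_oracle(self, rng):
        p = rng.uniform(size=1000)
        assert np.allclose(bh_adjust(p), bh_oracle(p))


class TestTemporalProfile:
    def _simulated(self):
        # plenty of null genes so the induced set barely shifts the TPM
        # normalisation of the rest
        params = DEParams(
            n_genes=500, n_de_genes=5, log2_effect=2.0, noise_sd=0.1,
            samples_per_group=3,
        )
        sim = simulate_expression(params, seed=11)
        sheet = SampleSheet(sim.sample_sheet)
        tpm_by_day = {}
        for day in sheet.days:
            cols = sim.sample_sheet.loc[
                sim.sample_sheet["day"] == day, "sample"
            ]
            tpm_by_day[day] = compute_tpm(
                sim.counts[list(cols)], sim.effective_lengths
            )
        return sim, sheet, tpm_by_day

    def test_planted_genes_ramp_to_final_day(self):
        sim, sheet, tpm_by_day = self._simulated()
        table = temporal_profile(
            tpm_by_day, sheet, "control", "anti-PD1", genes=sim.de_genes
        )
        assert (table["argmax_day"] == 17).mean() >= 0.9
        assert table["is_monotone_increasing"].mean() >= 0.9

    def test_flat_genes_near_zero_difference(self):
        sim, sheet, tpm_by_day = self._simulated()
        null_genes = [g for g in sim.counts.index if g not in set(sim.de_genes)]
        table = temporal_profile(
            tpm_by_day, sheet, "control", "anti-PD1", genes=null_genes[:50]
        )
        for day in (11, 14, 17):
            assert table[f"diff_d{day}"].abs().mean() < 0.2
        assert table["is_monotone_increasing"].mean() < 0.5

    def test_argmax_matches_naive_row_oracle(self):
        sim, sheet, tpm_by_day = self._simulated()
        table = temporal_profile(tpm_by_day, sheet, "control", "anti-PD1")
        diffs = table[[f"diff_d{d}" for d in (11, 14, 17)]].to_numpy()
        expected = [(11, 14, 17)[i] for i in diffs.argmax(axis=1)]
        assert list(table["argmax_day"]) == expected


class TestVolcano:
    def _results(self, q, fc):
        return pd.DataFrame(
            {"log2fc": fc, "t_stat": 0.0, "p_value": q, "q_value": q},
            index=[f"g{i}" for i in range(len(q))],
        )

    def test_boundary_q_not_significant_under_strict_cutoff(self):
        table = volcano_table(self._results([0.05], [1.0]))
        assert table.loc[0, "y"] == pytest.approx(-math.log10(0.05))
        assert not table.loc[0, "significant"]

    def test_q_one_maps_to_zero(self):
        assert volcano_table(self._results([1.0], [0.0])).loc[0, "y"] == 0.0

    def test_q_zero_floored_before_log(self):
        y = volcano_table(self._results([0.0], [2.0])).loc[0, "y"]
        assert np.isfinite(y)

    def test_row_conservation(self, rng):
        q = rng.uniform(size=37)
        assert len(volcano_table(self._results(q, q))) == 37


def test_differential_expression_end_to_end_recovers_planted():
    params = DEParams(n_genes=400, n_de_genes=20, samples_per_group=4)
    sim = simulate_expression(params, seed=3)
    sheet = SampleSheet(sim.sample_sheet)
    tpm = compute_tpm(sim.counts, sim.effective_lengths)
    res = differential_expression(tpm, sheet, "control", "anti-PD1", day=17)
    planted = res.loc[sim.de_genes]
    assert (planted["q_value"] < 0.05).mean() >= 0.8
    assert (res["q_value"] >= res["p_value"] - 1e-12).all()


def test_differential_expression_rejects_single_sample_group():
    params = DEParams(n_genes=50, n_de_genes=5, samples_per_group=2)
    sim = simulate_expression(params, seed=5)
    sheet_df = sim.sample_sheet[
        ~(
            (sim.sample_sheet["group"] == "control")
            & (sim.sample_sheet["day"] == 17)
            & (sim.sample_sheet["sample"].str.endswith("r2"))
        )
    ]
    tpm = compute_tpm(sim.counts, sim.effective_lengths)
    with pytest.raises(DEError, match="2 samples"):
        differential_expression(tpm, SampleSheet(sheet_df), "control", "anti-PD1", day=17)
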