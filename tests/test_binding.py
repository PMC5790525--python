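"""Matrix predictor scoring, consensus combination, and matrix file IO."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neoscout.binding import (
    BindingPrediction,
    MatrixFormatError,
    PredictorRegistry,
    ScoringMatrix,
    consensus_ic50,
    load_scoring_matrix,
    predict_ic50,
    predict_ic50_many,
    write_scoring_matrix,
)
from neoscout.epitopes import H2_KB, PeptideCandidate
from neoscout.sequence import AMINO_ACIDS, MissenseChange, SomaticVariant

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _matrix(weights, intercept=2.0, k=8, predictor="p1"):
    return ScoringMatrix(
        allele="H-2Kb", length=k, weights=weights, intercept=intercept,
        predictor_id=predictor,
    )


def _candidate(peptide="SIINFEKL"):
    variant = SomaticVariant(
        gene="g", transcript_id="tx", change=MissenseChange("Y", 4, peptide[3])
    )
    wt = peptide[:3] + "Y" + peptide[4:]
    return PeptideCandidate(
        variant=variant,
        allele=H2_KB,
        mutant_peptide=peptide,
        wildtype_peptide=wt,
        window_start=1,
        mut_offset=4,
    )


class TestPredictIc50:
    def test_zero_weights_give_intercept_power(self):
        m = _matrix(np.zeros((20, 8)), intercept=2.0)
        assert predict_ic50(m, "SIINFEKL") == pytest.approx(100.0)

    def test_single_weight_contribution(self):
        w = np.zeros((20, 8))
        w[_AA_INDEX["S"], 0] = 1.0
        m = _matrix(w, intercept=0.0)
        assert predict_ic50(m, "SIINFEKL") == pytest.approx(10.0)

    def test_length_mismatch_raises(self):
        m = _matrix(np.zeros((20, 8)))
        with pytest.raises(ValueError):
            predict_ic50(m, "SIINFEK")

    def test_invalid_residue_raises(self):
        m = _matrix(np.zeros((20, 8)))
        with pytest.raises(ValueError, match="X"):
            predict_ic50(m, "SIINFEKX")

    def test_clamped_to_bounds(self):
        low = _matrix(np.full((20, 8), -5.0), intercept=0.0)
        high = _matrix(np.full((20, 8), 5.0), intercept=0.0)
        assert predict_ic50(low, "SIINFEKL") == 0.01
        assert predict_ic50(high, "SIINFEKL") == 1e7

    @given(data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_matches_naive_loop_oracle(self, data):
        k = data.draw(st.integers(8, 10))
        weights = np.array(
            data.draw(
                st.lists(
                    st.lists(
                        st.floats(-0.4, 0.4, allow_nan=False), min_size=k, max_size=k
                    ),
                    min_size=20,
                    max_size=20,
                )
            )
        )
        intercept = data.draw(st.floats(1.0, 5.0))
        peptide = data.draw(st.text(alphabet=AMINO_ACIDS, min_size=k, max_size=k))
        m = ScoringMatrix("a", k, weights, intercept, "p")
        expected_log = intercept
        for i, aa in enumerate(peptide):
            expected_log += weights[_AA_INDEX[aa]][i]
        assert predict_ic50(m, peptide) == pytest.approx(
            min(max(10**expected_log, 0.01), 1e7)
        )

    def test_monotone_in_used_weight(self, rng):
        weights = rng.normal(0, 0.2, (20, 8))
        peptide = "SIINFEKL"
        base = predict_ic50(_matrix(weights, intercept=3.0), peptide)
        bumped = weights.copy()
        bumped[_AA_INDEX["N"], 3] += 0.5
        assert predict_ic50(_matrix(bumped, intercept=3.0), peptide) > base

    def test_vectorised_scoring_matches_scalar(self, rng):
        weights = rng.normal(0, 0.2, (20, 8))
        m = _matrix(weights, intercept=3.5)
        peptides = ["".join(rng.choice(list(AMINO_ACIDS), 8)) for _ in range(30)]
        many = predict_ic50_many(m, peptides)
        for p, v in zip(peptides, many):
            assert v == pytest.approx(predict_ic50(m, p))


class TestConsensus:
    def _preds(self, values, cand=None):
        cand = cand or _candidate()
        return [
            BindingPrediction(candidate=cand, predictor_id=f"p{i}", ic50_nM=v)
            for i, v in enumerate(values)
        ]

    def test_single_predictor_identity(self):
        assert consensus_ic50(self._preds([42.0])) == pytest.approx(42.0)

    def test_geometric_mean_of_two(self):
        assert consensus_ic50(self._preds([10.0, 1000.0])) == pytest.approx(100.0)

    def test_linear_scale_option(self):
        assert consensus_ic50(self._preds([10.0, 1000.0]), scale="linear") == \
            pytest.approx(505.0)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            consensus_ic50([])

    def test_mixed_candidates_raise(self):
        preds = self._preds([10.0]) + self._preds([20.0], cand=_candidate("SIINFEKM"))
        with pytest.raises(ValueError, match="mix"):
            consensus_ic50(preds)

    @given(
        st.lists(st.floats(0.01, 1e7, allow_nan=False), min_size=1, max_size=7),
        st.randoms(),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_permutation_invariant(self, values, random):
        preds = self._preds(values)
        result = consensus_ic50(preds)
        assert min(values) - 1e-9 <= result <= max(values) + 1e-9
        # independent oracle: 10 ** mean(log10)
        oracle = 10 ** (sum(math.log10(v) for v in values) / len(values))
        assert result == pytest.approx(oracle, rel=1e-9)
        shuffled = list(preds)
        random.shuffle(shuffled)
        assert consensus_ic50(shuffled) == pytest.approx(result, rel=1e-12)


class TestMatrixIO:
    def test_write_read_round_trip(self, tmp_path, rng):
        m = _matrix(rng.normal(0, 0.3, (20, 8)), intercept=4.25, predictor="smm1")
        path = tmp_path / "m.tsv"
        write_scoring_matrix(m, path)
        loaded = load_scoring_matrix(path)
        assert loaded.allele == m.allele
        assert loaded.length == 8
        assert loaded.intercept == m.intercept
        assert np.array_equal(loaded.weights, m.weights)

    def test_missing_residue_row_named(self, tmp_path, rng):
        m = _matrix(rng.normal(0, 0.3, (20, 8)))
        path = tmp_path / "m.tsv"
        write_scoring_matrix(m, path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("W\t")]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(MatrixFormatError, match="W"):
            load_scoring_matrix(path)

    def test_column_count_mismatch_rejected(self, tmp_path, rng):
        m = _matrix(rng.normal(0, 0.3, (20, 9)), k=9)
        path = tmp_path / "m.tsv"
        write_scoring_matrix(m, path)
        path.write_text(path.read_text().replace("#length=9", "#length=8"))
        with pytest.raises(MatrixFormatError, match="columns"):
            load_scoring_matrix(path)

    def test_non_numeric_cell_rejected(self, tmp_path, rng):
        m = _matrix(rng.normal(0, 0.3, (20, 8)))
        path = tmp_path / "m.tsv"
        write_scoring_matrix(m, path)
        text = path.read_text().splitlines()
        fields = text[4].split("\t")
        fields[1] = "abc"
        text[4] = "\t".join(fields)
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(MatrixFormatError, match="non-numeric"):
            load_scoring_matrix(path)


class TestRegistry:
    def test_consensus_uses_all_predictors_for_allele_length(self, rng):
        cand = _candidate()
        matrices = [
            _matrix(rng.normal(0, 0.1, (20, 8)), intercept=3.0, predictor=f"smm{i}")
            for i in range(5)
        ]
        registry = PredictorRegistry(matrices)
        result = registry.predict_candidate(cand)
        assert len(result.per_predictor) == 5
        values = [p.ic50_nM for p in result.per_predictor]
        assert min(values) <= result.consensus_ic50_nM <= max(values)

    def test_missing_allele_length_raises(self):
        registry = PredictorRegistry([_matrix(np.zeros((20, 9)), k=9)])
        with pytest.raises(ValueError, match="no matrices"):
            registry.predict_candidate(_candidate())
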