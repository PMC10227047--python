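"""Syntax metric definitions: worked examples, oracle equivalence, invariants."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from speechsyntax.metrics import (
    EmptyTranscriptError,
    clause_token_rates,
    clause_type_rates,
    compute_syntax_profile,
    descriptive_counts,
    sentence_weighted_score,
)
from speechsyntax.types import CLAUSE_TYPES, ClauseType, SentenceAnnotation, Transcript

from conftest import oracle_recount, random_transcript


def S(count=5, coord=False, clauses=None, tokens=None):
    return SentenceAnnotation(
        token_count=count, is_coordinated=coord, subordinate_clauses=clauses or {}, tokens=tokens
    )


# a transcript exercising every sentence category, reused across tests:
# S1 simple; S2 coordinated-only; S3 complex {relative, causal};
# S4 coordinated-and-complex {causal}
FOUR = Transcript(
    "four",
    (
        S(3),
        S(6, coord=True),
        S(8, clauses={"relative": 1, "causal": 1}),
        S(10, coord=True, clauses={"causal": 1}),
    ),
)


class TestWeightedScore:
    def test_worked_example_two_relative_two_causal_one_complement_scores_15(self):
        s = S(clauses={"relative": 2, "causal": 2, "complement": 1})
        assert len(s.distinct_types) == 3  # the type factor
        assert sentence_weighted_score(s) == 15

    @pytest.mark.parametrize(
        "clauses,expected",
        [({}, 0), ({"temporal": 3}, 3), ({"relative": 1}, 1), ({"modal": 2, "final": 1}, 6)],
    )
    def test_score_is_clause_count_times_distinct_types(self, clauses, expected):
        assert sentence_weighted_score(S(clauses=clauses)) == expected


class TestDescriptives:
    def test_hand_counted_tokens_types_ttr_mlu(self):
        tr = Transcript("p", (S(5, tokens=("the", "man", "sees", "the", "dog")),))
        prof = descriptive_counts(tr)
        assert prof.total_words == 5
        assert prof.total_different_words == 4
        assert prof.ttr == pytest.approx(0.8)
        assert prof.mlu == pytest.approx(5.0)

    def test_type_count_is_case_folded(self):
        tr = Transcript("p", (S(3, tokens=("The", "the", "THE")),))
        assert descriptive_counts(tr).total_different_words == 1

    def test_empty_transcript_reports_missing_not_zero_division(self):
        prof = descriptive_counts(Transcript("p", ()))
        assert prof.total_words == 0
        assert prof.total_sentences == 0
        assert prof.mlu is None and prof.ttr is None

    def test_mlu_without_word_strings(self):
        prof = descriptive_counts(Transcript("p", (S(10), S(4))))
        assert prof.mlu == pytest.approx(7.0)
        assert prof.ttr is None and prof.total_different_words is None


class TestProfile:
    def test_four_sentence_hand_count(self):
        prof = compute_syntax_profile(FOUR)
        assert prof.relative_sum_sub == pytest.approx(0.5)
        assert prof.extended_relative_sum_sub == pytest.approx(0.75)
        assert prof.pure_syntactic_complexity == pytest.approx(1.5)
        assert prof.weighted_sum_sub == pytest.approx(1.25)  # (2*2 + 1*1) / 4
        assert prof.syntactic_diversity == pytest.approx(2 / 13)
        assert prof.rate_simple == pytest.approx(0.25)
        assert prof.rate_coordinated == pytest.approx(0.5)

    def test_all_simple_transcript_has_no_subordination(self):
        prof = compute_syntax_profile(Transcript("p", (S(), S(), S())))
        assert prof.relative_sum_sub == 0
        assert prof.extended_relative_sum_sub == 0
        assert prof.weighted_sum_sub == 0
        assert prof.syntactic_diversity == 0
        assert prof.pure_syntactic_complexity is None

    def test_minimal_complex_transcript(self):
        prof = compute_syntax_profile(Transcript("p", (S(clauses={"relative": 1}),)))
        assert prof.relative_sum_sub == 1
        assert prof.extended_relative_sum_sub == 1
        assert prof.pure_syntactic_complexity == 1
        assert prof.weighted_sum_sub == 1
        assert prof.syntactic_diversity == pytest.approx(1 / 13)

    def test_zero_sentence_transcript_raises(self):
        with pytest.raises(EmptyTranscriptError):
            compute_syntax_profile(Transcript("p", ()))


class TestClauseTypeRates:
    def test_four_sentence_rates(self):
        rates = clause_type_rates(FOUR)
        assert rates[ClauseType.RELATIVE] == pytest.approx(0.25)
        assert rates[ClauseType.CAUSAL] == pytest.approx(0.5)
        others = [t for t in CLAUSE_TYPES if t not in (ClauseType.RELATIVE, ClauseType.CAUSAL)]
        assert all(rates[t] == 0.0 for t in others)

    def test_all_simple_rates_zero_filled(self):
        rates = clause_type_rates(Transcript("p", (S(),)))
        assert set(rates) == set(CLAUSE_TYPES)
        assert all(v == 0.0 for v in rates.values())

    def test_rates_are_sentence_level_not_clause_level(self):
        tr = Transcript("p", (S(clauses={"complement": 2}), S(clauses={"complement": 2})))
        assert clause_type_rates(tr)[ClauseType.COMPLEMENT] == pytest.approx(1.0)
        assert clause_token_rates(tr)[ClauseType.COMPLEMENT] == pytest.approx(2.0)

    def test_zero_sentences_error(self):
        with pytest.raises(EmptyTranscriptError):
            clause_type_rates(Transcript("p", ()))


class TestOracleEquivalence:
    @given(st.integers(0, 10_000))
    def test_profile_matches_independent_recount(self, seed):
        tr = random_transcript(np.random.default_rng(seed))
        prof = compute_syntax_profile(tr)
        oracle = oracle_recount(tr)
        for key, expected in oracle.items():
            got = getattr(prof, key)
            if expected is None:
                assert got is None
            elif key == "per_type_rate":
                assert all(math.isclose(got[t], expected[t]) for t in CLAUSE_TYPES)
            else:
                assert got == pytest.approx(expected), key


class TestInvariants:
    @given(st.integers(0, 5000))
    def test_relative_le_extended_le_weighted_and_ranges(self, seed):
        tr = random_transcript(np.random.default_rng(seed))
        prof = compute_syntax_profile(tr)
        assert 0 <= prof.relative_sum_sub <= 1
        assert prof.relative_sum_sub <= prof.extended_relative_sum_sub
        assert prof.extended_relative_sum_sub <= prof.weighted_sum_sub + 1e-12
        assert 0 <= prof.syntactic_diversity <= 1
        if prof.pure_syntactic_complexity is not None:
            assert prof.pure_syntactic_complexity >= 1

    @given(st.integers(0, 5000))
    def test_category_rates_cover_taxonomy_with_overlap(self, seed):
        tr = random_transcript(np.random.default_rng(seed))
        prof = compute_syntax_profile(tr)
        total = prof.rate_simple + prof.rate_coordinated + prof.relative_sum_sub
        n_both = sum(1 for s in tr if s.is_coordinated and s.is_complex)
        assert total >= 1 - 1e-12
        if n_both == 0:
            assert total == pytest.approx(1.0)
        else:
            assert total > 1

    @given(st.integers(0, 5000))
    def test_appending_complex_sentence_is_monotone_in_totals(self, seed):
        rng = np.random.default_rng(seed)
        tr = random_transcript(rng)
        extra = SentenceAnnotation(
            token_count=4, subordinate_clauses={"concessive": int(rng.integers(1, 3))}
        )
        before = compute_syntax_profile(tr)
        after = compute_syntax_profile(Transcript(tr.participant_id, tr.sentences + (extra,)))
        n0, n1 = before.total_sentences, after.total_sentences
        assert after.extended_relative_sum_sub * n1 >= before.extended_relative_sum_sub * n0
        assert after.weighted_sum_sub * n1 >= before.weighted_sum_sub * n0
        assert after.syntactic_diversity >= before.syntactic_diversity

    @given(st.integers(0, 5000))
    def test_duplicating_every_sentence_leaves_headline_measures_unchanged(self, seed):
        tr = random_transcript(np.random.default_rng(seed))
        doubled = Transcript(tr.participant_id, tr.sentences + tr.sentences)
        a, b = compute_syntax_profile(tr), compute_syntax_profile(doubled)
        for m in ("relative_sum_sub", "extended_relative_sum_sub",
                  "pure_syntactic_complexity", "weighted_sum_sub", "syntactic_diversity"):
            va, vb = getattr(a, m), getattr(b, m)
            if va is None:
                assert vb is None
            else:
                assert vb == pytest.approx(va)


class TestTypes:
    def test_clause_taxonomy_has_exactly_13_labels_and_rejects_others(self):
        assert len(CLAUSE_TYPES) == 13
        with pytest.raises(ValueError, match="bogus"):
            S(clauses={"bogus": 1})

    def test_sentence_category_predicates(self):
        plain = S()
        both = S(coord=True, clauses={"modal": 1})
        assert plain.is_simple and not plain.is_complex
        assert both.is_complex and both.is_coordinated and not both.is_simple

    def test_tokens_length_must_match_count(self):
        with pytest.raises(ValueError, match="token_count"):
            S(count=3, tokens=("a", "b"))
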