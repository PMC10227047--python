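"""Transcript-level descriptive and syntactic complexity / diversity measures.

Five headline measures quantify subordination in a transcript:

* ``relative_sum_sub`` — share of sentences embedding at least one
  subordinate clause (complex sentences / total sentences).  Depth of
  embedding is ignored: one embedded clause counts like four.
* ``extended_relative_sum_sub`` — all subordinate-clause tokens / total
  sentences; unlike the relative sum it credits multiple clauses per
  main clause.
* ``pure_syntactic_complexity`` — subordinate clauses per *complex*
  sentence, i.e. complexity free of the diluting effect of non-complex
  sentences; undefined (missing) when a transcript has no complex sentence.
* ``weighted_sum_sub`` — per-sentence weighted scores summed and divided by
  total sentences.  A sentence's score is its number of subordinate clauses
  multiplied by the number of *distinct* clause types it uses, so a main
  clause with 2 relative + 2 causal + 1 complement clauses scores
  5 x 3 = 15.
* ``syntactic_diversity`` — distinct clause types used anywhere in the
  transcript divided by the 13 possible types.

Descriptives (tokens, types, sentences, MLU, TTR) and per-type sentence
rates round out the profile.  All rates are relative to the total number of
sentences.  Missing quantities are ``None``, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Dict, List, Optional

from .types import CLAUSE_TYPES, N_CLAUSE_TYPES, ClauseType, SentenceAnnotation, Transcript


class EmptyTranscriptError(ValueError):
    """Raised when a syntax profile is requested for a zero-sentence transcript."""


@dataclass
class SyntaxProfile:
    """Descriptive counts plus the five headline syntax measures."""

    total_words: int = 0
    total_sentences: int = 0
    total_different_words: Optional[int] = None
    mlu: Optional[float] = None
    ttr: Optional[float] = None
    rate_simple: Optional[float] = None
    rate_coordinated: Optional[float] = None
    relative_sum_sub: Optional[float] = None
    extended_relative_sum_sub: Optional[float] = None
    pure_syntactic_complexity: Optional[float] = None
    weighted_sum_sub: Optional[float] = None
    syntactic_diversity: Optional[float] = None
    per_type_rate: Optional[Dict[ClauseType, float]] = None

    def as_row(self) -> Dict[str, Optional[float]]:
        """Flatten to a CSV-ready mapping; per-type rates become rate_<label>."""
        row: Dict[str, Optional[float]] = {}
        for f in fields(self):
            if f.name == "per_type_rate":
                continue
            row[f.name] = getattr(self, f.name)
        for t in CLAUSE_TYPES:
            row[f"rate_{t.value}"] = None if self.per_type_rate is None else self.per_type_rate[t]
        return row


#: Column order of the flattened profile row.
PROFILE_COLUMNS: List[str] = [f.name for f in fields(SyntaxProfile) if f.name != "per_type_rate"] + [
    f"rate_{t.value}" for t in CLAUSE_TYPES
]

#: The five headline measures, in reporting order.
HEADLINE_MEASURES: List[str] = [
    "relative_sum_sub",
    "extended_relative_sum_sub",
    "pure_syntactic_complexity",
    "weighted_sum_sub",
    "syntactic_diversity",
]


def descriptive_counts(transcript: Transcript) -> SyntaxProfile:
    """Token/type/sentence totals, MLU and TTR (headline fields left unset).

    ``total_different_words`` counts case-folded word strings and is missing
    whenever any sentence lacks token strings; MLU and TTR are missing for
    degenerate (zero-sentence / zero-word) transcripts.
    """
    total_sentences = len(transcript)
    total_words = sum(s.token_count for s in transcript)
    profile = SyntaxProfile(total_words=total_words, total_sentences=total_sentences)
    if total_sentences > 0:
        profile.mlu = total_words / total_sentences
    if total_sentences > 0 and all(s.tokens is not None for s in transcript):
        vocab = {w.casefold() for s in transcript for w in s.tokens}  # type: ignore[union-attr]
        profile.total_different_words = len(vocab)
        if total_words > 0:
            profile.ttr = len(vocab) / total_words
    return profile


def sentence_weighted_score(sentence: SentenceAnnotation) -> int:
    """Number of subordinate clauses x number of distinct types; 0 if non-complex."""
    return sentence.n_subordinate * len(sentence.distinct_types)


def clause_type_rates(transcript: Transcript) -> Dict[ClauseType, float]:
    """Share of sentences containing >= 1 clause of each type (zero-filled)."""
    n = len(transcript)
    if n == 0:
        raise EmptyTranscriptError("clause-type rates need at least one sentence")
    counts = {t: 0 for t in CLAUSE_TYPES}
    for s in transcript:
        for t in s.distinct_types:
            counts[t] += 1
    return {t: counts[t] / n for t in CLAUSE_TYPES}


def clause_token_rates(transcript: Transcript) -> Dict[ClauseType, float]:
    """Secondary convention: clause *tokens* of each type per sentence."""
    n = len(transcript)
    if n == 0:
        raise EmptyTranscriptError("clause-token rates need at least one sentence")
    counts = {t: 0 for t in CLAUSE_TYPES}
    for s in transcript:
        for t, c in s.subordinate_clauses.items():
            counts[t] += c
    return {t: counts[t] / n for t in CLAUSE_TYPES}


def compute_syntax_profile(transcript: Transcript) -> SyntaxProfile:
    """Full profile of a transcript: descriptives + the five headline measures.

    Raises
    ------
    EmptyTranscriptError
        For a zero-sentence transcript (no rate is computable).
    """
    n = len(transcript)
    if n == 0:
        raise EmptyTranscriptError(
            f"transcript {transcript.participant_id!r} has no sentences; no profile computable"
        )
    profile = descriptive_counts(transcript)

    n_complex = sum(1 for s in transcript if s.is_complex)
    n_clauses = sum(s.n_subordinate for s in transcript)
    weighted_total = sum(sentence_weighted_score(s) for s in transcript)
    types_used = set()
    for s in transcript:
        types_used |= s.distinct_types

    profile.rate_simple = sum(1 for s in transcript if s.is_simple) / n
    profile.rate_coordinated = sum(1 for s in transcript if s.is_coordinated) / n
    profile.relative_sum_sub = n_complex / n
    profile.extended_relative_sum_sub = n_clauses / n
    profile.pure_syntactic_complexity = n_clauses / n_complex if n_complex else None
    profile.weighted_sum_sub = weighted_total / n
    profile.syntactic_diversity = len(types_used) / N_CLAUSE_TYPES
    profile.per_type_rate = clause_type_rates(transcript)
    return profile
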