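"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from speechsyntax.types import CLAUSE_TYPES, SentenceAnnotation, Transcript

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def oracle_recount(transcript: Transcript) -> dict:
    """Independent sentence-by-sentence recount of every syntax measure.

    Deliberately written as plain accumulation loops, separate from the
    implementation under test.
    """
    n_sent = 0
    n_words = 0
    n_simple = 0
    n_coord = 0
    n_complex = 0
    n_clauses = 0
    weighted = 0
    types_seen = set()
    sentences_with_type = {t: 0 for t in CLAUSE_TYPES}
    for s in transcript.sentences:
        n_sent += 1
        n_words += s.token_count
        total_here = 0
        kinds_here = set()
        for t, c in s.subordinate_clauses.items():
            total_here += c
            kinds_here.add(t)
        if total_here == 0 and not s.is_coordinated:
            n_simple += 1
        if s.is_coordinated:
            n_coord += 1
        if total_here > 0:
            n_complex += 1
            n_clauses += total_here
            weighted += total_here * len(kinds_here)
            for t in kinds_here:
                types_seen.add(t)
                sentences_with_type[t] += 1
    out = {
        "total_words": n_words,
        "total_sentences": n_sent,
        "rate_simple": n_simple / n_sent if n_sent else None,
        "rate_coordinated": n_coord / n_sent if n_sent else None,
        "relative_sum_sub": n_complex / n_sent if n_sent else None,
        "extended_relative_sum_sub": n_clauses / n_sent if n_sent else None,
        "pure_syntactic_complexity": n_clauses / n_complex if n_complex else None,
        "weighted_sum_sub": weighted / n_sent if n_sent else None,
        "syntactic_diversity": len(types_seen) / 13,
        "per_type_rate": {t: sentences_with_type[t] / n_sent for t in CLAUSE_TYPES}
        if n_sent
        else None,
    }
    return out


def random_transcript(rng: np.random.Generator, n_sentences: int | None = None,
                      with_tokens: bool = False) -> Transcript:
    """Small random transcript for property tests (independent of simulate.py)."""
    if n_sentences is None:
        n_sentences = int(rng.integers(1, 12))
    sentences = []
    for _ in range(n_sentences):
        count = int(rng.integers(0, 20))
        clauses = {}
        for t in CLAUSE_TYPES:
            if rng.random() < 0.15:
                clauses[t.value] = int(rng.integers(1, 4))
        tokens = tuple(f"tok{rng.integers(0, 30)}" for _ in range(count)) if with_tokens else None
        sentences.append(
            SentenceAnnotation(
                token_count=count,
                is_coordinated=bool(rng.random() < 0.4),
                subordinate_clauses=clauses,
                tokens=tokens,
            )
        )
    return Transcript("rand", tuple(sentences))


@pytest.fixture(scope="session")
def default_cohort():
    """One default three-group cohort at the published sizes (34/38/40)."""
    from speechsyntax.simulate import CohortConfig, sample_cohort

    return sample_cohort(CohortConfig(), seed=20230529)


@pytest.fixture(scope="session")
def default_cohort_frame(default_cohort):
    from speechsyntax.simulate import cohort_frame

    return cohort_frame(default_cohort)
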