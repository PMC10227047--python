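"""Domain types for annotated spontaneous-speech transcripts.

A transcript is a participant's sequence of complete utterances ("sentences").
Each sentence carries a structural annotation produced by a human rater: how
many word tokens it contains, whether it is a coordinated sentence, and the
multiset of subordinate clauses embedded in it.  Thirteen subordinate-clause
types are distinguished: ten adverbial types plus relative clauses, complement
clauses and indirect questions.  Embedding depth is deliberately not encoded —
all subordinate clauses of a sentence live in one flat multiset.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Tuple


class ClauseType(str, Enum):
    """The 13 subordinate-clause types tracked in the annotation scheme."""

    TEMPORAL = "temporal"
    LOCAL = "local"
    MODAL = "modal"
    CAUSAL = "causal"
    CONDITIONAL = "conditional"
    ADVERSATIVE = "adversative"
    FINAL = "final"
    CONSECUTIVE = "consecutive"
    CONCESSIVE = "concessive"
    COMPARATIVE = "comparative"
    RELATIVE = "relative"
    COMPLEMENT = "complement"
    INDIRECT_QUESTION = "indirect_question"

    @classmethod
    def from_label(cls, label: str) -> "ClauseType":
        try:
            return cls(label)
        except ValueError:
            raise ValueError(
                f"unknown clause type label {label!r}; expected one of "
                f"{[t.value for t in cls]}"
            ) from None


#: Canonical ordering of the 13 types (adverbial types first).
CLAUSE_TYPES: Tuple[ClauseType, ...] = tuple(ClauseType)
N_CLAUSE_TYPES: int = len(CLAUSE_TYPES)
assert N_CLAUSE_TYPES == 13


@dataclass(frozen=True)
class SentenceAnnotation:
    """Structural annotation of one complete utterance.

    Parameters
    ----------
    token_count
        Number of word tokens in the utterance (>= 0).
    is_coordinated
        Whether the utterance is a coordinated sentence (clauses joined by
        conjunctions or enumeration).
    subordinate_clauses
        Multiset of embedded subordinate clauses.  A sentence with at least
        one subordinate clause is *complex*; a sentence may be both
        coordinated and complex, but a *simple* sentence is neither.
    tokens
        Optional word strings; when present their number must equal
        ``token_count``.  Word identity is only needed for type counts / TTR.
    """

    token_count: int
    is_coordinated: bool = False
    subordinate_clauses: Counter = field(default_factory=Counter)
    tokens: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.token_count < 0:
            raise ValueError("token_count must be non-negative")
        clauses = Counter(
            {ClauseType.from_label(t): c for t, c in dict(self.subordinate_clauses).items()}
        )
        for t, c in clauses.items():
            if c <= 0 or c != int(c):
                raise ValueError(f"clause multiplicity for {t.value} must be a positive integer")
        object.__setattr__(self, "subordinate_clauses", clauses)
        if self.tokens is not None:
            toks = tuple(self.tokens)
            if len(toks) != self.token_count:
                raise ValueError(
                    f"tokens has length {len(toks)} but token_count is {self.token_count}"
                )
            object.__setattr__(self, "tokens", toks)

    @property
    def n_subordinate(self) -> int:
        return sum(self.subordinate_clauses.values())

    @property
    def is_complex(self) -> bool:
        return self.n_subordinate >= 1

    @property
    def is_simple(self) -> bool:
        return not self.is_coordinated and self.n_subordinate == 0

    @property
    def distinct_types(self) -> frozenset:
        return frozenset(self.subordinate_clauses)


@dataclass(frozen=True)
class Transcript:
    """A participant's ordered, annotated utterances."""

    participant_id: str
    sentences: Tuple[SentenceAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ValueError("participant_id must be non-empty")
        object.__setattr__(self, "sentences", tuple(self.sentences))

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)


def make_clause_multiset(labels: Iterable[str] | Mapping[str, int]) -> Counter:
    """Build a subordinate-clause multiset from labels or a label->count map."""
    if isinstance(labels, Mapping):
        return Counter({ClauseType.from_label(str(k)): int(v) for k, v in labels.items() if v})
    return Counter(ClauseType.from_label(str(x)) for x in labels)
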