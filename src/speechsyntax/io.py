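"""File formats: transcript annotation files, profile and cohort tables.

The transcript annotation format is line oriented, one sentence per record,
with columns

    participant_id  sentence_index  token_count  is_coordinated  subordinate_clauses  [tokens]

as tab-separated values (with a header line) where ``subordinate_clauses`` is
a semicolon-joined list of clause-type labels (empty allowed) and ``tokens``
is an optional space-joined word list.  A JSON-lines dialect with the same
field names (clauses and tokens as JSON arrays) is read and written
interchangeably; files ending in ``.jsonl`` are treated as JSON lines.

Validation is strict: unknown clause labels, malformed lines and duplicate
(participant, sentence_index) pairs are rejected with the offending line
number.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .metrics import PROFILE_COLUMNS, SyntaxProfile
from .types import SentenceAnnotation, Transcript, make_clause_multiset

logger = logging.getLogger(__name__)

TSV_COLUMNS = [
    "participant_id",
    "sentence_index",
    "token_count",
    "is_coordinated",
    "subordinate_clauses",
    "tokens",
]

#: Float formatting used by every table writer, so reruns are byte-identical.
FLOAT_FORMAT = "%.10g"


class TranscriptFormatError(ValueError):
    """Malformed transcript annotation input."""


def _is_jsonl(path: Path) -> bool:
    return path.suffix.lower() in {".jsonl", ".json", ".ndjson"}


def write_transcripts(transcripts: Sequence[Transcript], path: str | Path) -> None:
    """Write transcripts in the TSV (default) or JSON-lines annotation format."""
    path = Path(path)
    if _is_jsonl(path):
        with path.open("w") as fh:
            for tr in transcripts:
                for i, s in enumerate(tr.sentences):
                    rec = {
                        "participant_id": tr.participant_id,
                        "sentence_index": i,
                        "token_count": s.token_count,
                        "is_coordinated": int(s.is_coordinated),
                        "subordinate_clauses": sorted(
                            t.value for t in s.subordinate_clauses.elements()
                        ),
                    }
                    if s.tokens is not None:
                        rec["tokens"] = list(s.tokens)
                    fh.write(json.dumps(rec) + "\n")
        return
    with path.open("w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for tr in transcripts:
            for i, s in enumerate(tr.sentences):
                clauses = ";".join(sorted(t.value for t in s.subordinate_clauses.elements()))
                base = (
                    f"{tr.participant_id}\t{i}\t{s.token_count}\t"
                    f"{int(s.is_coordinated)}\t{clauses}"
                )
                # 5 fields: no token strings; 6th field (possibly empty): strings present
                if s.tokens is None:
                    fh.write(base + "\n")
                else:
                    fh.write(base + "\t" + " ".join(s.tokens) + "\n")


def _parse_tsv_line(line: str, lineno: int) -> Tuple[str, int, SentenceAnnotation]:
    parts = line.rstrip("\n").split("\t")
    has_tokens_field = len(parts) == 6
    if len(parts) == 5:
        parts = parts + [""]
    if len(parts) != 6:
        raise TranscriptFormatError(
            f"line {lineno}: expected 5 or 6 tab-separated fields, got {len(parts)}"
        )
    pid, idx_s, count_s, coord_s, clauses_s, tokens_s = parts
    if not pid:
        raise TranscriptFormatError(f"line {lineno}: empty participant_id")
    try:
        idx = int(idx_s)
        count = int(count_s)
        coord = int(coord_s)
    except ValueError as exc:
        raise TranscriptFormatError(f"line {lineno}: {exc}") from None
    if coord not in (0, 1):
        raise TranscriptFormatError(f"line {lineno}: is_coordinated must be 0 or 1, got {coord_s!r}")
    labels = [x for x in clauses_s.split(";") if x] if clauses_s else []
    try:
        clauses = make_clause_multiset(labels)
        if tokens_s:
            tokens = tuple(tokens_s.split(" "))
        elif has_tokens_field and count == 0:
            tokens = ()
        else:
            tokens = None
        sentence = SentenceAnnotation(
            token_count=count, is_coordinated=bool(coord), subordinate_clauses=clauses, tokens=tokens
        )
    except ValueError as exc:
        raise TranscriptFormatError(f"line {lineno}: {exc}") from None
    return pid, idx, sentence


def _parse_jsonl_line(line: str, lineno: int) -> Tuple[str, int, SentenceAnnotation]:
    try:
        rec = json.loads(line)
    except json.JSONDecodeError as exc:
        raise TranscriptFormatError(f"line {lineno}: invalid JSON ({exc})") from None
    try:
        pid = str(rec["participant_id"])
        idx = int(rec["sentence_index"])
        tokens = rec.get("tokens")
        sentence = SentenceAnnotation(
            token_count=int(rec["token_count"]),
            is_coordinated=bool(rec["is_coordinated"]),
            subordinate_clauses=make_clause_multiset(rec.get("subordinate_clauses", [])),
            tokens=tuple(tokens) if tokens is not None else None,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise TranscriptFormatError(f"line {lineno}: {exc}") from None
    if not pid:
        raise TranscriptFormatError(f"line {lineno}: empty participant_id")
    return pid, idx, sentence


def read_transcripts(path: str | Path) -> List[Transcript]:
    """Read validated transcripts from the TSV or JSON-lines annotation format.

    Sentence order within a participant follows ``sentence_index``; duplicate
    (participant, sentence_index) pairs are an error.  An empty file yields an
    empty list with a logged warning.
    """
    path = Path(path)
    jsonl = _is_jsonl(path)
    per_participant: Dict[str, Dict[int, SentenceAnnotation]] = {}
    order: List[str] = []
    n_records = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not jsonl and lineno == 1 and line.split("\t")[0] == "participant_id":
                continue  # header
            pid, idx, sentence = (_parse_jsonl_line if jsonl else _parse_tsv_line)(line, lineno)
            bucket = per_participant.setdefault(pid, {})
            if pid not in order:
                order.append(pid)
            if idx in bucket:
                raise TranscriptFormatError(
                    f"line {lineno}: duplicate sentence_index {idx} for participant {pid!r}"
                )
            bucket[idx] = sentence
            n_records += 1
    if n_records == 0:
        logger.warning("no sentence records found in %s", path)
        return []
    return [
        Transcript(pid, tuple(s for _, s in sorted(per_participant[pid].items())))
        for pid in order
    ]


def profiles_to_frame(profiles: Dict[str, SyntaxProfile]) -> pd.DataFrame:
    """One row per participant, columns = flattened SyntaxProfile fields."""
    rows = []
    for pid, profile in profiles.items():
        row = {"participant_id": pid}
        row.update(profile.as_row())
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["participant_id"] + PROFILE_COLUMNS)
    return frame


def write_profiles(profiles: Dict[str, SyntaxProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Deterministic CSV/TSV writer (missing values as empty cells)."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    frame.to_csv(path, index=index, sep=sep, float_format=FLOAT_FORMAT, na_rep="")
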