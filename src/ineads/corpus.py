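"""Reading, filtering and normalising clinical note and admission tables.

The expected on-disk layout follows the common de-identified critical-care
EHR convention: a note-events CSV with one row per document (free text in a
quoted, possibly multiline field) and an admissions CSV with one row per
hospital stay. Column names are configurable and default to the NOTEEVENTS /
ADMISSIONS-style headers (``ROW_ID``, ``SUBJECT_ID``, ``HADM_ID``,
``CATEGORY``, ``CHARTTIME``, ``TEXT``).

Preprocessing is deliberately light: lowercase, punctuation-stripping
tokenization, a small function-word stopword list, and replacement of
de-identification placeholders (``[** ... **]``) by a sentinel token.
Negation cues such as "no", "not" and "denies" are never treated as
stopwords because downstream negation detection depends on them.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Note",
    "Admission",
    "TokenizedNote",
    "DEID_SENTINEL",
    "DEFAULT_INCLUDED_CATEGORIES",
    "DEFAULT_NOTE_COLUMNS",
    "DEFAULT_ADMISSION_COLUMNS",
    "default_stopwords",
    "read_notes",
    "write_notes",
    "read_admissions",
    "write_admissions",
    "preprocess",
    "tokenize",
    "normalize_term",
    "sentences_of",
]

#: Sentinel standing in for any de-identification placeholder span.
DEID_SENTINEL = "xxdeidxx"

_DEID_RE = re.compile(r"\[\*\*.*?\*\*\]", re.DOTALL)
# Word runs; intra-word hyphens are kept ("half-way" stays one token),
# slashes and all other punctuation split.
_TOKEN_RE = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)
_SENTENCE_PUNCT = set(".?!;\n")

#: Note categories retained by default: document types likely to carry
#: social, directive or capacity information.
DEFAULT_INCLUDED_CATEGORIES = frozenset(
    {
        "case management",
        "consultation",
        "discharge summary",
        "nursing",
        "nutrition",
        "physician",
        "rehabilitation",
        "respiratory",
        "social work",
        "general",
    }
)

#: Categories recognised but excluded by default (diagnostic/report types
#: unlikely to mention social context).
KNOWN_EXCLUDED_CATEGORIES = frozenset(
    {"radiology", "pharmacy", "echocardiogram", "ecg", "echo"}
)

DEFAULT_NOTE_COLUMNS: Mapping[str, str] = {
    "note_id": "ROW_ID",
    "patient_id": "SUBJECT_ID",
    "admission_id": "HADM_ID",
    "category": "CATEGORY",
    "chart_time": "CHARTTIME",
    "text": "TEXT",
}

DEFAULT_ADMISSION_COLUMNS: Mapping[str, str] = {
    "admission_id": "HADM_ID",
    "patient_id": "SUBJECT_ID",
    "age": "AGE",
    "gender": "GENDER",
    "ethnicity": "ETHNICITY",
    "admission_type": "ADMISSION_TYPE",
    "insurance": "INSURANCE",
    "expired_in_hospital": "HOSPITAL_EXPIRE_FLAG",
    "expired_in_followup": "FOLLOWUP_EXPIRE_FLAG",
}

ADMISSION_TYPES = frozenset({"elective", "emergency", "urgent"})


class CorpusFormatError(ValueError):
    """Raised when an input table cannot be parsed or violates an invariant."""


@dataclass(frozen=True)
class Note:
    """One clinical document tied to an admission."""

    note_id: str
    patient_id: str
    admission_id: str
    category: str
    chart_time: str | None
    text: str

    def __post_init__(self) -> None:
        if self.text is None:
            raise CorpusFormatError(f"note {self.note_id}: text must not be null")


@dataclass(frozen=True)
class Admission:
    """One hospital stay with the demographics used for cohort comparison."""

    admission_id: str
    patient_id: str
    age: float
    gender: str
    ethnicity: str
    admission_type: str
    insurance: str
    expired_in_hospital: bool
    expired_in_followup: bool

    def __post_init__(self) -> None:
        if self.age < 0:
            raise CorpusFormatError(f"admission {self.admission_id}: age < 0")
        if self.expired_in_hospital and not self.expired_in_followup:
            raise CorpusFormatError(
                f"admission {self.admission_id}: expired_in_hospital implies "
                "expired_in_followup"
            )


@dataclass(frozen=True)
class TokenizedNote:
    """Preprocessed view of a note.

    ``tokens`` are the surviving normalized tokens, ``token_offsets`` the
    character span each token came from, and ``sentence_breaks`` the set of
    token indices *before* which a sentence boundary (period, newline, ...)
    occurs in the raw text.
    """

    note_id: str
    tokens: tuple[str, ...]
    token_offsets: tuple[tuple[int, int], ...]
    sentence_breaks: frozenset[int]

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.token_offsets:
            if start < prev_end or end <= start:
                raise ValueError("token offsets must be increasing and non-overlapping")
            prev_end = end


_STOPWORDS_CACHE: frozenset[str] | None = None


def default_stopwords() -> frozenset[str]:
    """The packaged ~30-word function-word list."""
    global _STOPWORDS_CACHE
    if _STOPWORDS_CACHE is None:
        text = resources.files("ineads.data").joinpath("stopwords.txt").read_text()
        _STOPWORDS_CACHE = frozenset(w for w in text.split() if w)
    return _STOPWORDS_CACHE


def tokenize(
    text: str, stopwords: frozenset[str] | None = None
) -> tuple[tuple[str, ...], tuple[tuple[int, int], ...], frozenset[int]]:
    """Tokenize raw note text.

    Returns ``(tokens, offsets, sentence_breaks)``. De-identification
    placeholders become :data:`DEID_SENTINEL` (their span covers the whole
    bracketed region); stopwords are removed entirely.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    raw: list[tuple[int, int, str]] = []
    pos = 0
    for m in _DEID_RE.finditer(text):
        for tm in _TOKEN_RE.finditer(text, pos, m.start()):
            raw.append((tm.start(), tm.end(), tm.group().lower()))
        raw.append((m.start(), m.end(), DEID_SENTINEL))
        pos = m.end()
    for tm in _TOKEN_RE.finditer(text, pos):
        raw.append((tm.start(), tm.end(), tm.group().lower()))

    tokens: list[str] = []
    offsets: list[tuple[int, int]] = []
    breaks: set[int] = set()
    prev_end: int | None = None
    for start, end, tok in raw:
        if tok in stopwords:
            continue
        if prev_end is not None and _SENTENCE_PUNCT & set(text[prev_end:start]):
            breaks.add(len(tokens))
        tokens.append(tok)
        offsets.append((start, end))
        prev_end = end
    return tuple(tokens), tuple(offsets), frozenset(breaks)


def preprocess(note: Note, stopwords: frozenset[str] | None = None) -> TokenizedNote:
    """Lowercase, strip punctuation/stopwords and mask de-id placeholders."""
    tokens, offsets, breaks = tokenize(note.text, stopwords)
    return TokenizedNote(note.note_id, tokens, offsets, breaks)


def normalize_term(term: str, stopwords: frozenset[str] | None = None) -> tuple[str, ...]:
    """Normalize a lexicon term with the corpus tokenizer.

    Matching is exact on normalized token sequences, so terms must go
    through the identical pipeline as note text.
    """
    tokens, _, _ = tokenize(term, stopwords)
    return tokens


def sentences_of(tnote: TokenizedNote) -> list[list[str]]:
    """Split a tokenized note into sentences at its recorded boundaries."""
    sentences: list[list[str]] = []
    current: list[str] = []
    for i, tok in enumerate(tnote.tokens):
        if i in tnote.sentence_breaks and current:
            sentences.append(current)
            current = []
        current.append(tok)
    if current:
        sentences.append(current)
    return sentences


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pandas reports the offending row
        raise CorpusFormatError(f"{path}: malformed CSV row ({exc})") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise CorpusFormatError(f"{path}: missing required columns {missing}")
    return frame


def read_notes(
    path: str | Path,
    included_categories: Iterable[str] | None = None,
    columns: Mapping[str, str] | None = None,
    unknown_category: str = "drop",
) -> list[Note]:
    """Read a note-events CSV, keeping only the included categories.

    Parameters
    ----------
    included_categories
        Note categories to retain (case-insensitive). Defaults to the
        document types likely to carry social/directive information.
    unknown_category
        What to do with rows whose category is neither included nor in the
        known excluded set: ``"drop"`` (warn and drop, the default),
        ``"error"``, or ``"keep"``.
    """
    if unknown_category not in ("drop", "error", "keep"):
        raise ValueError("unknown_category must be 'drop', 'error' or 'keep'")
    cols = dict(DEFAULT_NOTE_COLUMNS)
    if columns:
        cols.update(columns)
    included = frozenset(
        c.strip().lower()
        for c in (included_categories if included_categories is not None
                  else DEFAULT_INCLUDED_CATEGORIES)
    )
    frame = _read_table(path, [cols[k] for k in ("note_id", "category", "text")])

    notes: list[Note] = []
    n_excluded = 0
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        record = dict(zip(frame.columns, row))
        category = record[cols["category"]].strip().lower()
        if category not in included:
            known = category in KNOWN_EXCLUDED_CATEGORIES or category in DEFAULT_INCLUDED_CATEGORIES
            if not known and unknown_category == "error":
                raise CorpusFormatError(
                    f"{path} row {row_number}: unknown note category {category!r}"
                )
            if known or unknown_category in ("drop", "error"):
                if not known:
                    warnings.warn(
                        f"dropping note with unknown category {category!r} "
                        f"(row {row_number})",
                        stacklevel=2,
                    )
                n_excluded += 1
                continue
        notes.append(
            Note(
                note_id=record[cols["note_id"]],
                patient_id=record.get(cols["patient_id"], ""),
                admission_id=record.get(cols["admission_id"], ""),
                category=category,
                chart_time=record.get(cols["chart_time"]) or None,
                text=record[cols["text"]],
            )
        )
    if n_excluded:
        warnings.warn(f"read_notes: excluded {n_excluded} rows by category", stacklevel=2)
    return notes


def write_notes(
    notes: Iterable[Note],
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> None:
    """Write notes back to CSV in the configured schema (round-trip safe)."""
    cols = dict(DEFAULT_NOTE_COLUMNS)
    if columns:
        cols.update(columns)
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, quoting=csv.QUOTE_ALL)
        writer.writerow([cols[k] for k in DEFAULT_NOTE_COLUMNS])
        for note in notes:
            writer.writerow(
                [
                    note.note_id,
                    note.patient_id,
                    note.admission_id,
                    note.category,
                    note.chart_time or "",
                    note.text,
                ]
            )


def _parse_flag(value: str, where: str) -> bool:
    value = value.strip().lower()
    if value in ("1", "true", "t", "yes", "y"):
        return True
    if value in ("0", "false", "f", "no", "n", ""):
        return False
    raise CorpusFormatError(f"{where}: cannot parse boolean flag {value!r}")


def read_admissions(
    path: str | Path,
    min_age: float = 18,
    columns: Mapping[str, str] | None = None,
) -> list[Admission]:
    """Read an admissions CSV, excluding patients younger than ``min_age``."""
    if min_age < 0:
        raise ValueError("min_age must be >= 0")
    cols = dict(DEFAULT_ADMISSION_COLUMNS)
    if columns:
        cols.update(columns)
    frame = _read_table(path, [cols["admission_id"], cols["age"]])

    admissions: list[Admission] = []
    seen: set[str] = set()
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        record = dict(zip(frame.columns, row))
        admission_id = record[cols["admission_id"]]
        if admission_id in seen:
            raise CorpusFormatError(
                f"{path} row {row_number}: duplicate admission_id {admission_id!r}"
            )
        seen.add(admission_id)
        try:
            age = float(record[cols["age"]])
        except ValueError as exc:
            raise CorpusFormatError(
                f"{path} row {row_number}: cannot parse age {record[cols['age']]!r}"
            ) from exc
        if age < min_age:
            continue
        where = f"{path} row {row_number}"
        admissions.append(
            Admission(
                admission_id=admission_id,
                patient_id=record.get(cols["patient_id"], ""),
                age=age,
                gender=record.get(cols["gender"], "").strip().lower(),
                ethnicity=record.get(cols["ethnicity"], "").strip().lower(),
                admission_type=record.get(cols["admission_type"], "").strip().lower(),
                insurance=record.get(cols["insurance"], "").strip().lower(),
                expired_in_hospital=_parse_flag(
                    record.get(cols["expired_in_hospital"], ""), where
                ),
                expired_in_followup=_parse_flag(
                    record.get(cols["expired_in_followup"], ""), where
                ),
            )
        )
    return admissions


def write_admissions(
    admissions: Iterable[Admission],
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> None:
    cols = dict(DEFAULT_ADMISSION_COLUMNS)
    if columns:
        cols.update(columns)
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, quoting=csv.QUOTE_ALL)
        writer.writerow([cols[k] for k in DEFAULT_ADMISSION_COLUMNS])
        for adm in admissions:
            writer.writerow(
                [
                    adm.admission_id,
                    adm.patient_id,
                    f"{adm.age:g}",
                    adm.gender,
                    adm.ethnicity,
                    adm.admission_type,
                    adm.insurance,
                    int(adm.expired_in_hospital),
                    int(adm.expired_in_followup),
                ]
            )
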