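"""Negation-aware detection of lexicon terms in preprocessed notes.

Matching is exact on normalized token sequences — recall comes from
vocabulary expansion, not fuzzy matching. Overlapping candidate matches are
resolved longest-match-first, then leftmost; a token participates in at most
one mention per subcategory (overlap across subcategories is allowed, which
is exactly how nested vocabulary such as "wife" inside "estranged from his
wife" produces cross-category hits).

Negation follows a NegEx-style windowed rule: a mention is negated when a
forward trigger ("no", "not", "denies", ...) occurs within ``scope`` tokens
before it, or a backward trigger within ``scope`` tokens after it, with no
intervening sentence boundary or adversative conjunction. Terms that
themselves begin with a negation token ("no living will", "no contact from
family") carry their negation as part of their meaning and are exempt —
they are never flagged.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import corpus
from .corpus import Note, TokenizedNote
from .lexicon import Lexicon

__all__ = [
    "Mention",
    "NoteAnnotation",
    "NegationConfig",
    "CorpusSummary",
    "default_negation_config",
    "find_mentions",
    "detect_negation",
    "annotate_note",
    "annotate_corpus",
    "write_annotations_jsonl",
    "read_annotations_jsonl",
    "write_mentions_tsv",
]


@dataclass(frozen=True)
class Mention:
    """One matched lexicon term in one note."""

    note_id: str
    subcategory: str
    term: str
    token_span: tuple[int, int]  # half-open token indices
    char_span: tuple[int, int]
    negated: bool = False


@dataclass(frozen=True)
class NoteAnnotation:
    """All mentions found in one note.

    ``subcategories_present`` is derived: subcategories with at least one
    non-negated mention. Negated mentions are retained for audit.
    """

    note_id: str
    mentions: tuple[Mention, ...]

    @property
    def subcategories_present(self) -> frozenset[str]:
        return frozenset(m.subcategory for m in self.mentions if not m.negated)


@dataclass(frozen=True)
class NegationConfig:
    forward_triggers: frozenset[str]
    backward_triggers: frozenset[str]
    scope: int = 6
    scope_breakers: frozenset[str] = frozenset({"but"})

    def __post_init__(self) -> None:
        if self.scope < 1:
            raise ValueError("negation scope must be >= 1")


_DEFAULT_NEGATION: NegationConfig | None = None


def default_negation_config() -> NegationConfig:
    """Packaged trigger list (~15 forward, 5 backward), scope of 6 tokens."""
    global _DEFAULT_NEGATION
    if _DEFAULT_NEGATION is None:
        text = resources.files("ineads.data").joinpath("negation_triggers.tsv").read_text()
        forward, backward = set(), set()
        for row in csv.DictReader(text.splitlines(), delimiter="\t"):
            (forward if row["direction"] == "forward" else backward).add(row["trigger"])
        _DEFAULT_NEGATION = NegationConfig(frozenset(forward), frozenset(backward))
    return _DEFAULT_NEGATION


def load_negation_config(path: str | Path, scope: int = 6) -> NegationConfig:
    forward, backward = set(), set()
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            (forward if row["direction"] == "forward" else backward).add(row["trigger"])
    return NegationConfig(frozenset(forward), frozenset(backward), scope=scope)


def find_mentions(tnote: TokenizedNote, lexicon: Lexicon) -> list[Mention]:
    """All maximal lexicon matches in a tokenized note (negation not applied).

    The note must have been preprocessed with the same tokenizer/stopword
    configuration as the lexicon terms.
    """
    tokens = tnote.tokens
    index = lexicon.token_index()
    candidates: list[tuple[int, int, str, str]] = []
    for i, tok in enumerate(tokens):
        for entry in index.get(tok, ()):
            n = len(entry.tokens)
            if tokens[i : i + n] == entry.tokens:
                candidates.append((i, i + n, entry.subcategory, entry.term))

    # longest first, then leftmost, then lexicographic term for determinism
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2], c[3]))
    taken: dict[str, set[int]] = {}
    accepted: list[tuple[int, int, str, str]] = []
    for start, end, subcat, term in candidates:
        used = taken.setdefault(subcat, set())
        span = range(start, end)
        if any(i in used for i in span):
            continue
        used.update(span)
        accepted.append((start, end, subcat, term))

    accepted.sort(key=lambda c: (c[0], c[1], c[2]))
    return [
        Mention(
            note_id=tnote.note_id,
            subcategory=subcat,
            term=term,
            token_span=(start, end),
            char_span=(tnote.token_offsets[start][0], tnote.token_offsets[end - 1][1]),
        )
        for start, end, subcat, term in accepted
    ]


def _blocked(breaks: frozenset[int], breakers: set[int], lo: int, hi: int) -> bool:
    """Is the token path (lo, hi] interrupted by a boundary or breaker token?

    A sentence break at index b separates tokens b-1 and b; it blocks when
    lo < b <= hi. A breaker token at index j blocks when lo < j < hi.
    """
    return any(lo < b <= hi for b in breaks) or any(lo < j < hi for j in breakers)


def detect_negation(
    tnote: TokenizedNote,
    mentions: Sequence[Mention],
    config: NegationConfig | None = None,
) -> list[Mention]:
    """Flag mentions governed by a negation trigger within scope."""
    if config is None:
        config = default_negation_config()
    tokens = tnote.tokens
    forward = [i for i, t in enumerate(tokens) if t in config.forward_triggers]
    backward = [i for i, t in enumerate(tokens) if t in config.backward_triggers]
    breakers = {i for i, t in enumerate(tokens) if t in config.scope_breakers}
    breaks = tnote.sentence_breaks

    out: list[Mention] = []
    for mention in mentions:
        start, end = mention.token_span
        first_token = mention.term.split()[0] if mention.term else ""
        if first_token in config.forward_triggers:
            out.append(replace(mention, negated=False))  # negation is part of the term
            continue
        negated = any(
            start - config.scope <= t < start and not _blocked(breaks, breakers, t, start)
            for t in forward
        ) or any(
            end <= t <= end - 1 + config.scope
            and not _blocked(breaks, breakers, end - 1, t)
            for t in backward
        )
        out.append(replace(mention, negated=negated))
    return out


def annotate_note(
    note: Note,
    lexicon: Lexicon,
    negation: NegationConfig | None = None,
    stopwords: frozenset[str] | None = None,
) -> NoteAnnotation:
    """Preprocess one note, find mentions, and apply negation."""
    tnote = corpus.preprocess(note, stopwords)
    mentions = detect_negation(tnote, find_mentions(tnote, lexicon), negation)
    return NoteAnnotation(note_id=note.note_id, mentions=tuple(mentions))


@dataclass
class CorpusSummary:
    """Corpus-level annotation counts."""

    n_notes: int = 0
    n_notes_with_subcategory: int = 0
    by_note_category: dict[str, dict[str, int]] = field(default_factory=dict)
    per_subcategory_notes: dict[str, int] = field(default_factory=dict)

    @property
    def fraction_with_subcategory(self) -> float:
        return self.n_notes_with_subcategory / self.n_notes if self.n_notes else 0.0

    def to_dict(self) -> dict:
        return {
            "n_notes": self.n_notes,
            "n_notes_with_subcategory": self.n_notes_with_subcategory,
            "fraction_with_subcategory": self.fraction_with_subcategory,
            "by_note_category": self.by_note_category,
            "per_subcategory_notes": self.per_subcategory_notes,
        }


def annotate_corpus(
    notes: Iterable[Note],
    lexicon: Lexicon,
    negation: NegationConfig | None = None,
    stopwords: frozenset[str] | None = None,
) -> tuple[dict[str, NoteAnnotation], CorpusSummary]:
    """Annotate every note; per-note results are order-independent."""
    annotations: dict[str, NoteAnnotation] = {}
    summary = CorpusSummary()
    for note in notes:
        annotation = annotate_note(note, lexicon, negation, stopwords)
        annotations[note.note_id] = annotation
        summary.n_notes += 1
        cat = summary.by_note_category.setdefault(
            note.category, {"n_notes": 0, "n_with_subcategory": 0}
        )
        cat["n_notes"] += 1
        present = annotation.subcategories_present
        if present:
            summary.n_notes_with_subcategory += 1
            cat["n_with_subcategory"] += 1
        for subcat in present:
            summary.per_subcategory_notes[subcat] = (
                summary.per_subcategory_notes.get(subcat, 0) + 1
            )
    summary.per_subcategory_notes = dict(sorted(summary.per_subcategory_notes.items()))
    return annotations, summary


def write_annotations_jsonl(
    annotations: Mapping[str, NoteAnnotation], path: str | Path
) -> None:
    """One JSON object per note: id, mention list, derived subcategory set."""
    with open(path, "w", encoding="utf-8") as handle:
        for note_id in annotations:
            annotation = annotations[note_id]
            record = {
                "note_id": annotation.note_id,
                "mentions": [
                    {
                        "subcategory": m.subcategory,
                        "term": m.term,
                        "token_span": list(m.token_span),
                        "char_span": list(m.char_span),
                        "negated": m.negated,
                    }
                    for m in annotation.mentions
                ],
                "subcategories_present": sorted(annotation.subcategories_present),
            }
            handle.write(json.dumps(record) + "\n")


def read_annotations_jsonl(path: str | Path) -> dict[str, NoteAnnotation]:
    annotations: dict[str, NoteAnnotation] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            record = json.loads(line)
            mentions = tuple(
                Mention(
                    note_id=record["note_id"],
                    subcategory=m["subcategory"],
                    term=m["term"],
                    token_span=tuple(m["token_span"]),
                    char_span=tuple(m["char_span"]),
                    negated=m["negated"],
                )
                for m in record["mentions"]
            )
            annotations[record["note_id"]] = NoteAnnotation(record["note_id"], mentions)
    return annotations


def write_mentions_tsv(
    annotations: Mapping[str, NoteAnnotation], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(
            ["note_id", "subcategory", "term", "negated", "token_start", "token_end",
             "char_start", "char_end"]
        )
        for note_id in annotations:
            for m in annotations[note_id].mentions:
                writer.writerow(
                    [m.note_id, m.subcategory, m.term, int(m.negated),
                     m.token_span[0], m.token_span[1], m.char_span[0], m.char_span[1]]
                )
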