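"""The 17-subcategory vocabulary of advance-directive / surrogate / capacity concepts.

Each subcategory belongs to one of three domains (surrogate decision makers,
advance directives, decisional capacity) and is annotated with whether its
documentation indicates *reduced* or *elevated* potential for the patient
being incapacitated with no evident advance directives or surrogates.
Five elevated subcategories describing the patient's social situation —
unmarried, living alone, transitionally situated, surrogate decision maker
unidentified, and advance directives unavailable — drive the cohort rules
and are flagged ``social_elevated``. Lacking decisional capacity is elevated
but not one of the social five.

Terms are stored pre-normalized with the corpus tokenizer so that matching
against preprocessed notes is tokenizer-consistent.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from . import corpus

__all__ = [
    "SubcategoryDef",
    "LexiconEntry",
    "Lexicon",
    "ValidationIssue",
    "SUBCATEGORIES",
    "SOCIAL_ELEVATED_FIVE",
    "REDUCED_SUBCATEGORIES",
    "seed_default_lexicon",
    "load_lexicon",
    "save_lexicon",
    "validate_lexicon",
]

DOMAINS = ("surrogate_decision_makers", "advance_directives", "decisional_capacity")
PROVENANCES = ("seed", "accepted_synonym")


@dataclass(frozen=True)
class SubcategoryDef:
    name: str
    domain: str
    potential: str  # "reduced" | "elevated"
    social_elevated: bool
    display_name: str


def _load_subcategories() -> dict[str, SubcategoryDef]:
    text = resources.files("ineads.data").joinpath("subcategories.tsv").read_text()
    out: dict[str, SubcategoryDef] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        out[row["name"]] = SubcategoryDef(
            name=row["name"],
            domain=row["domain"],
            potential=row["potential"],
            social_elevated=row["social_elevated"] == "1",
            display_name=row["display_name"],
        )
    return out


#: The fixed subcategory schema (17 entries).
SUBCATEGORIES: dict[str, SubcategoryDef] = _load_subcategories()

#: The five social subcategories behind the cohort rules.
SOCIAL_ELEVATED_FIVE: frozenset[str] = frozenset(
    name for name, sub in SUBCATEGORIES.items() if sub.social_elevated
)

#: Subcategories whose documentation indicates reduced potential.
REDUCED_SUBCATEGORIES: frozenset[str] = frozenset(
    name for name, sub in SUBCATEGORIES.items() if sub.potential == "reduced"
)


@dataclass(frozen=True)
class LexiconEntry:
    """One term mapped to one subcategory.

    ``term`` is a space-joined sequence of normalized tokens; ``provenance``
    records whether it came from the seed vocabulary or was accepted during
    embedding-driven expansion.
    """

    term: str
    subcategory: str
    provenance: str = "seed"

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(self.term.split())


class Lexicon:
    """An ordered, deduplicated collection of lexicon entries."""

    def __init__(self, entries: Iterable[LexiconEntry] = (), version: str = "0") -> None:
        self.version = version
        self._entries: dict[tuple[str, str], LexiconEntry] = {}
        self._index_cache: dict[str, list[LexiconEntry]] | None = None
        for entry in entries:
            self.add(entry)

    def add(self, entry: LexiconEntry) -> bool:
        """Add an entry; returns False (no-op) if the pair already exists."""
        if entry.subcategory not in SUBCATEGORIES:
            raise KeyError(
                f"unknown subcategory {entry.subcategory!r}; valid names: "
                f"{sorted(SUBCATEGORIES)}"
            )
        key = (entry.term, entry.subcategory)
        if key in self._entries:
            return False
        self._entries[key] = entry
        self._index_cache = None
        return True

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self._entries.values())

    def __contains__(self, key: object) -> bool:
        if isinstance(key, tuple):
            return key in self._entries
        return any(term == key for term, _ in self._entries)

    @property
    def entries(self) -> tuple[LexiconEntry, ...]:
        return tuple(self._entries.values())

    def lookup(self, term: str) -> list[LexiconEntry]:
        """All entries whose term equals ``term`` (normalized)."""
        normalized = " ".join(corpus.normalize_term(term))
        return [e for e in self if e.term == normalized]

    def subcategories_for(self, term: str) -> set[str]:
        return {e.subcategory for e in self.lookup(term)}

    def terms_for(self, subcategory: str) -> list[str]:
        if subcategory not in SUBCATEGORIES:
            raise KeyError(f"unknown subcategory {subcategory!r}")
        return [e.term for e in self if e.subcategory == subcategory]

    @property
    def max_term_tokens(self) -> int:
        return max((len(e.tokens) for e in self), default=0)

    def token_index(self) -> dict[str, list[LexiconEntry]]:
        """First-token index over non-empty entries, cached until mutation."""
        if self._index_cache is None:
            index: dict[str, list[LexiconEntry]] = {}
            for entry in self:
                if entry.tokens:
                    index.setdefault(entry.tokens[0], []).append(entry)
            self._index_cache = index
        return self._index_cache


def _normalized_entry(term: str, subcategory: str, provenance: str) -> LexiconEntry:
    normalized = " ".join(corpus.normalize_term(term))
    return LexiconEntry(normalized, subcategory, provenance)


_SEED_CACHE: tuple[LexiconEntry, ...] | None = None


def seed_default_lexicon() -> Lexicon:
    """The shipped seed vocabulary (sample terms plus curated obvious synonyms)."""
    global _SEED_CACHE
    if _SEED_CACHE is None:
        text = resources.files("ineads.data").joinpath("seed_lexicon.tsv").read_text()
        _SEED_CACHE = tuple(
            _normalized_entry(row["term"], row["subcategory"], row["provenance"])
            for row in csv.DictReader(text.splitlines(), delimiter="\t")
        )
    return Lexicon(_SEED_CACHE, version="seed-1")


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon TSV (term, subcategory, [provenance]).

    Duplicate (term, subcategory) pairs are deduplicated with a warning;
    an unknown subcategory raises, listing the valid names.
    """
    lexicon = Lexicon()
    n_dupes = 0
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            entry = _normalized_entry(
                row["term"], row["subcategory"], row.get("provenance") or "seed"
            )
            if not lexicon.add(entry):
                n_dupes += 1
    if n_dupes:
        warnings.warn(f"{path}: deduplicated {n_dupes} repeated lexicon entries")
    return lexicon


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["term", "subcategory", "provenance"])
        for entry in lexicon:
            writer.writerow([entry.term, entry.subcategory, entry.provenance])


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str


def validate_lexicon(lexicon: Lexicon) -> list[ValidationIssue]:
    """Report structural problems: empty terms, stopword-only content,
    cross-subcategory duplicate terms (allowed, flagged as warnings)."""
    issues: list[ValidationIssue] = []
    stopwords = corpus.default_stopwords()
    by_term: dict[str, list[str]] = {}
    for entry in lexicon:
        if not entry.term:
            issues.append(ValidationIssue("error", f"empty term in {entry.subcategory}"))
            continue
        if all(tok in stopwords for tok in entry.tokens):
            issues.append(
                ValidationIssue(
                    "error", f"stopword-only term {entry.term!r} in {entry.subcategory}"
                )
            )
        if entry.provenance not in PROVENANCES:
            issues.append(
                ValidationIssue(
                    "warning",
                    f"unrecognized provenance {entry.provenance!r} for {entry.term!r}",
                )
            )
        by_term.setdefault(entry.term, []).append(entry.subcategory)
    for term, subcats in by_term.items():
        if len(subcats) > 1:
            issues.append(
                ValidationIssue(
                    "warning",
                    f"term {term!r} appears in multiple subcategories: {sorted(subcats)}",
                )
            )
    return issues
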