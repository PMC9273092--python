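"""Scoring system annotations against adjudicated gold labels.

Evaluation is note-level and binary per subcategory: a true positive is a
note where both the system and the gold reviewers assign the subcategory, a
false positive is system-only, a false negative gold-only. Precision is
TP/(TP+FP) (positive predictive value), recall TP/(TP+FN) (sensitivity),
and the F-score their harmonic mean 2PR/(P+R). The overall row is the
unweighted macro average over subcategories that were observed at all (gold
or predicted); unobserved subcategories are reported as absent and excluded
from the mean. Documentation frequencies are reported over the notes that
carry at least one gold label.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .lexicon import SUBCATEGORIES
from .matcher import NoteAnnotation

__all__ = [
    "CategoryMetrics",
    "EvalReport",
    "f_score",
    "evaluate_annotations",
    "cohens_kappa",
    "frequency_table",
    "read_gold_jsonl",
    "write_gold_jsonl",
]


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class CategoryMetrics:
    subcategory: str
    tp: int
    fp: int
    fn: int
    gold_frequency: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f(self) -> float:
        return f_score(self.precision, self.recall)

    @property
    def observed(self) -> bool:
        return self.gold_frequency > 0 or self.tp + self.fp > 0


@dataclass
class EvalReport:
    per_category: dict[str, CategoryMetrics]
    n_notes: int
    n_labeled_notes: int

    @property
    def included(self) -> list[CategoryMetrics]:
        return [m for m in self.per_category.values() if m.observed]

    @property
    def overall_precision(self) -> float:
        included = self.included
        return sum(m.precision for m in included) / len(included) if included else 0.0

    @property
    def overall_recall(self) -> float:
        included = self.included
        return sum(m.recall for m in included) / len(included) if included else 0.0

    @property
    def overall_f(self) -> float:
        included = self.included
        return sum(m.f for m in included) / len(included) if included else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Tabular report: one row per subcategory (absent ones dashed) plus
        the macro overall row."""
        rows = []
        ordered = sorted(
            self.per_category.values(), key=lambda m: (-m.gold_frequency, m.subcategory)
        )
        for m in ordered:
            if m.observed:
                rows.append(
                    {
                        "subcategory": m.subcategory,
                        "gold_n": m.gold_frequency,
                        "gold_pct": (
                            round(100 * m.gold_frequency / self.n_labeled_notes, 1)
                            if self.n_labeled_notes
                            else None
                        ),
                        "precision": m.precision,
                        "recall": m.recall,
                        "f_score": m.f,
                    }
                )
            else:
                rows.append(
                    {
                        "subcategory": m.subcategory,
                        "gold_n": None, "gold_pct": None,
                        "precision": None, "recall": None, "f_score": None,
                    }
                )
        rows.append(
            {
                "subcategory": "overall",
                "gold_n": self.n_labeled_notes,
                "gold_pct": 100.0 if self.n_labeled_notes else None,
                "precision": self.overall_precision,
                "recall": self.overall_recall,
                "f_score": self.overall_f,
            }
        )
        return pd.DataFrame(rows)


def _as_label_sets(
    annotations: Mapping[str, NoteAnnotation] | Mapping[str, frozenset[str]],
) -> dict[str, frozenset[str]]:
    out: dict[str, frozenset[str]] = {}
    for note_id, value in annotations.items():
        if isinstance(value, NoteAnnotation):
            out[note_id] = value.subcategories_present
        else:
            out[note_id] = frozenset(value)
    return out


def evaluate_annotations(
    system: Mapping[str, NoteAnnotation] | Mapping[str, frozenset[str]],
    gold: Mapping[str, frozenset[str]],
) -> EvalReport:
    """Note-level binary comparison of system output against gold labels.

    The gold mapping defines the note universe; a system note outside it is
    an error. Notes in gold but absent from the system output count as
    all-negative system notes.
    """
    system_sets = _as_label_sets(system)
    gold_sets = {k: frozenset(v) for k, v in gold.items()}
    stray = set(system_sets) - set(gold_sets)
    if stray:
        raise KeyError(
            f"system notes outside the gold universe: {sorted(stray)[:5]}"
        )
    unknown = {
        s for labels in list(gold_sets.values()) + list(system_sets.values())
        for s in labels if s not in SUBCATEGORIES
    }
    if unknown:
        raise KeyError(f"unknown subcategories in labels: {sorted(unknown)}")

    per_category: dict[str, CategoryMetrics] = {}
    for subcategory in sorted(SUBCATEGORIES):
        tp = fp = fn = 0
        for note_id, gold_labels in gold_sets.items():
            in_gold = subcategory in gold_labels
            in_system = subcategory in system_sets.get(note_id, frozenset())
            tp += in_gold and in_system
            fp += in_system and not in_gold
            fn += in_gold and not in_system
        per_category[subcategory] = CategoryMetrics(
            subcategory=subcategory, tp=tp, fp=fp, fn=fn, gold_frequency=tp + fn
        )
    n_labeled = sum(1 for labels in gold_sets.values() if labels)
    return EvalReport(
        per_category=per_category, n_notes=len(gold_sets), n_labeled_notes=n_labeled
    )


def cohens_kappa(
    annotator_a: Mapping[str, bool] | Sequence[bool],
    annotator_b: Mapping[str, bool] | Sequence[bool],
) -> float:
    """Chance-corrected agreement between two binary labelings.

    kappa = (p_o - p_e) / (1 - p_e) with marginal expected agreement p_e.
    If both annotators are constant and identical, p_e = 1 and kappa is
    undefined; 1.0 is returned with a warning.
    """
    if isinstance(annotator_a, Mapping) != isinstance(annotator_b, Mapping):
        raise TypeError("annotators must both be mappings or both sequences")
    if isinstance(annotator_a, Mapping):
        if set(annotator_a) != set(annotator_b):
            raise ValueError("annotators must label the same note universe")
        keys = sorted(annotator_a)
        a = [bool(annotator_a[k]) for k in keys]
        b = [bool(annotator_b[k]) for k in keys]
    else:
        if len(annotator_a) != len(annotator_b):
            raise ValueError("annotators must label the same number of notes")
        a = [bool(x) for x in annotator_a]
        b = [bool(x) for x in annotator_b]
    n = len(a)
    if n == 0:
        raise ValueError("cannot compute agreement on an empty universe")
    p_o = sum(x == y for x, y in zip(a, b)) / n
    p_a = sum(a) / n
    p_b = sum(b) / n
    p_e = p_a * p_b + (1 - p_a) * (1 - p_b)
    if p_e == 1.0:
        warnings.warn(
            "both annotators are constant and identical; kappa undefined, "
            "reporting 1.0"
        )
        return 1.0
    return (p_o - p_e) / (1 - p_e)


def frequency_table(gold: Mapping[str, frozenset[str]]) -> pd.DataFrame:
    """Documentation counts and percentages per subcategory.

    Percentages are over the notes with at least one gold label.
    """
    gold_sets = {k: frozenset(v) for k, v in gold.items()}
    labeled = [labels for labels in gold_sets.values() if labels]
    denominator = len(labeled)
    rows = []
    counts: dict[str, int] = {}
    for labels in labeled:
        for subcategory in labels:
            counts[subcategory] = counts.get(subcategory, 0) + 1
    for subcategory, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        rows.append(
            {
                "subcategory": subcategory,
                "n": count,
                "pct": round(100 * count / denominator, 1),
            }
        )
    return pd.DataFrame(rows, columns=["subcategory", "n", "pct"])


def write_gold_jsonl(gold: Mapping[str, frozenset[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for note_id in gold:
            handle.write(
                json.dumps({"note_id": note_id, "subcategories": sorted(gold[note_id])})
                + "\n"
            )


def read_gold_jsonl(path: str | Path) -> dict[str, frozenset[str]]:
    gold: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            record = json.loads(line)
            if record["note_id"] in gold:
                raise ValueError(f"duplicate note_id {record['note_id']!r} in gold file")
            gold[record["note_id"]] = frozenset(record["subcategories"])
    return gold


def write_report(report: EvalReport, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    frame = report.to_frame()
    frame.to_csv(tsv_path, sep="\t", index=False, quoting=csv.QUOTE_MINIMAL)
    if json_path is not None:
        payload = {
            "overall": {
                "precision": report.overall_precision,
                "recall": report.overall_recall,
                "f_score": report.overall_f,
            },
            "per_category": {
                m.subcategory: {
                    "tp": m.tp, "fp": m.fp, "fn": m.fn,
                    "gold_frequency": m.gold_frequency,
                    "precision": m.precision if m.observed else None,
                    "recall": m.recall if m.observed else None,
                    "f_score": m.f if m.observed else None,
                }
                for m in report.per_category.values()
            },
        }
        with open(json_path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2)
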