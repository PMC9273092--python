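"""Admission-level aggregation, cohort classification, and cohort comparison.

A hospital admission's profile is the set union of the subcategories found
in any of its notes. The cohort rules operate on the five social
subcategories indicating elevated potential (unmarried, living alone,
transitionally situated, surrogate decision maker unidentified, advance
directives unavailable):

* ``possibility``     — at least one of the five is documented;
* ``high_likelihood`` — at least four of the five are documented,
  bifurcated by whether any reduced-potential subcategory is also present.

Cohort characteristics are compared against the full cohort with Welch
t-tests (age) and chi-square tests without continuity correction
(categoricals and mortality). The subcohort is contained in the full cohort,
so these tests are not independent-sample tests in the strict sense; they
are reported as descriptive comparisons.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .corpus import Admission, Note
from .lexicon import REDUCED_SUBCATEGORIES, SOCIAL_ELEVATED_FIVE, SUBCATEGORIES
from .matcher import NoteAnnotation

__all__ = [
    "AdmissionProfile",
    "CohortLabel",
    "CohortSummary",
    "CharacteristicTest",
    "aggregate_admission",
    "aggregate_admissions",
    "classify_ineads",
    "percentage",
    "summarize_cohorts",
    "compare_cohorts",
    "default_qualifying_patterns",
    "sample_gold_standard",
    "write_profiles_tsv",
]

POSSIBILITY_MIN = 1
HIGH_LIKELIHOOD_MIN = 4


@dataclass(frozen=True)
class AdmissionProfile:
    """Union of detected subcategories over an admission's notes."""

    admission_id: str
    subcategories_present: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.subcategories_present - set(SUBCATEGORIES)
        if unknown:
            raise KeyError(f"unknown subcategories in profile: {sorted(unknown)}")

    @property
    def n_social_elevated(self) -> int:
        return len(self.subcategories_present & SOCIAL_ELEVATED_FIVE)

    @property
    def has_reduced(self) -> bool:
        return bool(self.subcategories_present & REDUCED_SUBCATEGORIES)


@dataclass(frozen=True)
class CohortLabel:
    label: str  # none | possibility | high_likelihood
    bifurcation: str | None = None  # no_reduced_signal | has_reduced_signal

    _ORDER = ("none", "possibility", "high_likelihood")

    def __ge__(self, other: "CohortLabel") -> bool:
        return self._ORDER.index(self.label) >= self._ORDER.index(other.label)


def aggregate_admission(
    admission_id: str, annotations: Iterable[NoteAnnotation]
) -> AdmissionProfile:
    """Set-union of note-level subcategories for one admission."""
    present: set[str] = set()
    for annotation in annotations:
        present |= annotation.subcategories_present
    return AdmissionProfile(admission_id, frozenset(present))


def aggregate_admissions(
    annotations: Mapping[str, NoteAnnotation],
    notes: Iterable[Note],
    admission_ids: Iterable[str] | None = None,
) -> dict[str, AdmissionProfile]:
    """Group note annotations by admission and aggregate each.

    Every annotated note must map to a known admission via ``notes``;
    admissions without annotated notes get empty profiles when listed in
    ``admission_ids``.
    """
    note_to_admission = {n.note_id: n.admission_id for n in notes}
    missing = set(annotations) - set(note_to_admission)
    if missing:
        raise KeyError(f"annotated notes missing from note table: {sorted(missing)[:5]}")
    grouped: dict[str, list[NoteAnnotation]] = {}
    for note_id, annotation in annotations.items():
        grouped.setdefault(note_to_admission[note_id], []).append(annotation)
    ids = set(grouped)
    if admission_ids is not None:
        ids |= set(admission_ids)
    return {
        admission_id: aggregate_admission(admission_id, grouped.get(admission_id, ()))
        for admission_id in sorted(ids)
    }


def classify_ineads(
    profile: AdmissionProfile,
    possibility_min: int = POSSIBILITY_MIN,
    high_likelihood_min: int = HIGH_LIKELIHOOD_MIN,
) -> CohortLabel:
    """Apply the social-five thresholds to one admission profile."""
    n = profile.n_social_elevated
    if n >= high_likelihood_min:
        return CohortLabel(
            "high_likelihood",
            "has_reduced_signal" if profile.has_reduced else "no_reduced_signal",
        )
    if n >= possibility_min:
        return CohortLabel("possibility")
    return CohortLabel("none")


def percentage(count: int, total: int, ndigits: int = 0) -> float:
    """``100 * count / total`` rounded to the printed precision."""
    if total == 0:
        raise ZeroDivisionError("percentage of an empty cohort")
    value = round(100.0 * count / total, ndigits)
    return value if ndigits > 0 else float(int(value))


_CATEGORICALS = ("gender", "ethnicity", "admission_type", "insurance")
_BINARIES = ("expired_in_hospital", "expired_in_followup")


def _admission_frame(admissions: Sequence[Admission]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "admission_id": [a.admission_id for a in admissions],
            "age": [a.age for a in admissions],
            "gender": [a.gender for a in admissions],
            "ethnicity": [a.ethnicity for a in admissions],
            "admission_type": [a.admission_type for a in admissions],
            "insurance": [a.insurance for a in admissions],
            "expired_in_hospital": [a.expired_in_hospital for a in admissions],
            "expired_in_followup": [a.expired_in_followup for a in admissions],
        }
    )


@dataclass
class CohortSummary:
    """Long-form characteristic table per cohort plus headline counts."""

    table: pd.DataFrame
    cohort_n: dict[str, int]

    def to_json_dict(self) -> dict:
        return {
            "cohort_n": self.cohort_n,
            "rows": self.table.to_dict(orient="records"),
        }


def summarize_cohorts(
    admissions: Sequence[Admission],
    profiles: Mapping[str, AdmissionProfile],
) -> CohortSummary:
    """Characteristic counts and percentages for the full, possibility and
    high-likelihood cohorts."""
    missing = [a.admission_id for a in admissions if a.admission_id not in profiles]
    if missing:
        raise KeyError(f"profiles missing for admissions: {missing[:5]}")
    frame = _admission_frame(admissions)
    labels = {
        a.admission_id: classify_ineads(profiles[a.admission_id]).label
        for a in admissions
    }
    frame["label"] = frame["admission_id"].map(labels)
    cohorts = {
        "all": frame,
        "possibility": frame[frame["label"] != "none"],
        "high_likelihood": frame[frame["label"] == "high_likelihood"],
    }
    total = len(frame)
    rows: list[dict] = []
    for name, sub in cohorts.items():
        n = len(sub)
        rows.append(
            {
                "cohort": name, "characteristic": "n", "level": "",
                "n": n, "value": percentage(n, total, 1) if total else None,
            }
        )
        if n == 0:
            continue
        rows.append(
            {
                "cohort": name, "characteristic": "age", "level": "mean",
                "n": n, "value": float(sub["age"].mean()),
            }
        )
        rows.append(
            {
                "cohort": name, "characteristic": "age", "level": "sd",
                "n": n, "value": float(sub["age"].std(ddof=1)) if n > 1 else 0.0,
            }
        )
        for characteristic in _CATEGORICALS:
            for level, count in sub[characteristic].value_counts().sort_index().items():
                rows.append(
                    {
                        "cohort": name, "characteristic": characteristic,
                        "level": level, "n": int(count),
                        "value": percentage(int(count), n, 1),
                    }
                )
        for characteristic in _BINARIES:
            count = int(sub[characteristic].sum())
            rows.append(
                {
                    "cohort": name, "characteristic": characteristic, "level": "true",
                    "n": count, "value": percentage(count, n, 1),
                }
            )
    return CohortSummary(table=pd.DataFrame(rows), cohort_n={k: len(v) for k, v in cohorts.items()})


@dataclass(frozen=True)
class CharacteristicTest:
    characteristic: str
    test: str  # "welch_t" | "chi_square"
    statistic: float
    p_value: float

    @property
    def significant_05(self) -> bool:
        return self.p_value < 0.05

    @property
    def significant_001(self) -> bool:
        return self.p_value < 0.001


def compare_cohorts(
    full: Sequence[Admission], subcohort: Sequence[Admission]
) -> dict[str, CharacteristicTest]:
    """Test each characteristic of a subcohort against the full cohort.

    Age uses a Welch two-sample t-test; categorical characteristics and the
    mortality flags use chi-square on the level-count contingency table
    (no continuity correction). Raises if either cohort is empty or the
    subcohort is not contained in the full cohort.
    """
    if not full or not subcohort:
        raise ValueError("both cohorts must be non-empty")
    full_ids = {a.admission_id for a in full}
    if not {a.admission_id for a in subcohort} <= full_ids:
        raise ValueError("subcohort must be a subset of the full cohort")
    f_frame = _admission_frame(full)
    s_frame = _admission_frame(subcohort)

    results: dict[str, CharacteristicTest] = {}
    t_stat, t_p = stats.ttest_ind(
        s_frame["age"], f_frame["age"], equal_var=False
    )
    if np.isnan(t_stat):  # zero variance in both groups -> identical means
        t_stat, t_p = 0.0, 1.0
    results["age"] = CharacteristicTest("age", "welch_t", float(t_stat), float(t_p))

    for characteristic in _CATEGORICALS + _BINARIES:
        f_counts = f_frame[characteristic].value_counts()
        s_counts = s_frame[characteristic].value_counts()
        levels = sorted(set(f_counts.index) | set(s_counts.index))
        table = np.array(
            [
                [int(f_counts.get(level, 0)) for level in levels],
                [int(s_counts.get(level, 0)) for level in levels],
            ],
            dtype=float,
        )
        table = table[:, table.sum(axis=0) > 0]
        if table.size == 0:
            raise ValueError(f"{characteristic}: contingency table is all zero")
        if table.shape[1] < 2:
            # single level everywhere: no variation to test
            results[characteristic] = CharacteristicTest(
                characteristic, "chi_square", 0.0, 1.0
            )
            continue
        chi2 = stats.chi2_contingency(table, correction=False)
        results[characteristic] = CharacteristicTest(
            characteristic, "chi_square", float(chi2.statistic), float(chi2.pvalue)
        )
    return results


def default_qualifying_patterns() -> list[str]:
    """Shipped ICD-9 + ICD-10 prefix patterns for gold-standard eligibility."""
    text = resources.files("ineads.data").joinpath("qualifying_codes.yaml").read_text()
    config = yaml.safe_load(text)
    return list(config["icd9"]) + list(config["icd10"])


def _code_matches(code: str, patterns: Sequence[re.Pattern]) -> bool:
    stripped = code.replace(".", "").strip()
    return any(p.match(stripped) for p in patterns)


def sample_gold_standard(
    notes: Sequence[Note],
    diagnoses: Mapping[str, Iterable[str]],
    n: int,
    seed: int,
    qualifying_patterns: Sequence[str] | None = None,
    on_empty: str = "error",
) -> list[Note]:
    """Uniformly sample ``n`` notes from admissions with a qualifying diagnosis.

    ``diagnoses`` maps admission_id to its diagnosis codes; a code qualifies
    when it matches any pattern (regex on the dot-stripped code). The sample
    is without replacement and reproducible given ``seed``.
    """
    patterns = [
        re.compile(p, re.IGNORECASE)
        for p in (qualifying_patterns or default_qualifying_patterns())
    ]
    eligible_admissions = {
        admission_id
        for admission_id, codes in diagnoses.items()
        if any(_code_matches(str(code), patterns) for code in codes)
    }
    pool = [note for note in notes if note.admission_id in eligible_admissions]
    if not pool:
        if on_empty == "empty":
            return []
        raise ValueError("no notes belong to admissions with qualifying codes")
    if n > len(pool):
        raise ValueError(f"requested {n} notes but only {len(pool)} are eligible")
    rng = random.Random(seed)
    return rng.sample(pool, n)


def write_profiles_tsv(
    profiles: Mapping[str, AdmissionProfile], path: str
) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(
            ["admission_id", "subcategories", "n_social_elevated", "label",
             "bifurcation"]
        )
        for admission_id in sorted(profiles):
            profile = profiles[admission_id]
            label = classify_ineads(profile)
            writer.writerow(
                [
                    admission_id,
                    ",".join(sorted(profile.subcategories_present)),
                    profile.n_social_elevated,
                    label.label,
                    label.bifurcation or "",
                ]
            )
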