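"""Synthetic note corpora with known ground truth.

The generator emulates the structure of a de-identified critical-care
corpus: short telegraphic note sentences built from hand-written templates
in the style of real nursing/physician documentation, subcategory terms
planted per admission at configurable rates, negation triggers inserted at
a configurable rate, distractor sentences elsewhere, and an admissions
table with demographics sampled from configurable marginals. Everything is
driven by one seed, so the same configuration reproduces the same corpus
byte for byte.

Ground truth is exact by construction: the gold note labels are the
planted, non-negated mentions and the gold admission profiles their union.
The generator only plants *collision-free* terms — terms whose own text
does not also match a different subcategory (e.g. "never married" also
contains the married term "married") — so that the noiseless-recovery
contract (precision = recall = 1 with the seed lexicon) is well-posed.

It does NOT emulate the statistical texture of real clinical language
(spelling noise, section headers, copy-forward), so pipeline results on it
bound behaviour under ideal documentation only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import corpus as corpus_mod
from .cohort import CohortLabel, AdmissionProfile, classify_ineads
from .corpus import Admission, Note
from .lexicon import (
    Lexicon,
    REDUCED_SUBCATEGORIES,
    SUBCATEGORIES,
    seed_default_lexicon,
)
from .matcher import annotate_note, default_negation_config

__all__ = [
    "GeneratorConfig",
    "PlantRecord",
    "Substitution",
    "SyntheticCorpus",
    "load_templates",
    "held_out_synonyms",
    "plantable_vocabulary",
    "generate_corpus",
    "plant_synonyms",
    "end_to_end_truth",
]

#: Default per-admission planting probabilities. The four most frequently
#: documented subcategories use their published admission-level rates; the
#: five social-elevated subcategories use 0.07 each (their union under
#: independence is close to the published 30% possibility-cohort rate);
#: the remaining reduced subcategories get modest rates.
DEFAULT_PLANT_PROBS: Mapping[str, float] = {
    "relatives_unknown_involvement": 0.72,
    "lacking_capacity": 0.57,
    "surrogate_identified": 0.41,
    "advance_directives_available": 0.36,
    "married": 0.30,
    "partnered": 0.05,
    "caregiver_support": 0.05,
    "living_with_others": 0.07,
    "community_connection": 0.07,
    "religious_connections": 0.05,
    "palliative_care": 0.05,
    "hospice": 0.03,
    "unmarried": 0.07,
    "living_alone": 0.07,
    "transitionally_situated": 0.07,
    "surrogate_unidentified": 0.07,
    "advance_directives_unavailable": 0.07,
}

_ETHNICITIES = {"white": 0.71, "black": 0.14, "hispanic": 0.04, "other": 0.04, "unknown": 0.07}
_ADMISSION_TYPES = {"emergency": 0.86, "elective": 0.12, "urgent": 0.02}
_INSURANCES = {
    "medicare": 0.59, "private": 0.22, "medicaid": 0.14,
    "government": 0.04, "self pay": 0.01,
}
_NOTE_CATEGORIES = {"nursing": 0.70, "physician": 0.23, "social work": 0.04, "general": 0.03}

_QUALIFYING_CODES = ("29620", "30981", "3051", "01190", "07054", "042", "F329", "B182")
_OTHER_CODES = ("4019", "25000", "4280", "486", "5849", "41401")

_NEGATION_INSERTS = ("denies", "not")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus."""

    n_admissions: int = 1000
    mean_notes_per_admission: float = 3.0
    plant_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANT_PROBS)
    )
    negation_rate: float = 0.0
    synonym_substitution_rate: float = 0.0
    distractors_per_note: tuple[int, int] = (1, 3)
    age_mean: float = 61.0
    age_sd: float = 18.0
    age_bounds: tuple[float, float] = (18.0, 95.0)
    female_p: float = 0.54
    hospital_mortality_base: float = 0.09
    followup_mortality_base: float = 0.43
    mortality_enrichment: float = 0.10
    qualifying_dx_rate: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        probs = list(self.plant_probs.values()) + [
            self.negation_rate, self.synonym_substitution_rate,
            self.female_p, self.qualifying_dx_rate,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        unknown = set(self.plant_probs) - set(SUBCATEGORIES)
        if unknown:
            raise KeyError(f"plant_probs references unknown subcategories: {sorted(unknown)}")
        if self.n_admissions < 1:
            raise ValueError("n_admissions must be >= 1")


@dataclass(frozen=True)
class PlantRecord:
    note_id: str
    subcategory: str
    term: str
    surface: str  # the sentence as rendered into the note
    negated: bool


@dataclass(frozen=True)
class Substitution:
    note_id: str
    subcategory: str
    original_term: str
    substitute: str


@dataclass
class SyntheticCorpus:
    notes: list[Note]
    admissions: list[Admission]
    plants: list[PlantRecord]
    diagnoses: dict[str, list[str]]
    substitutions: list[Substitution]
    config: GeneratorConfig

    @property
    def gold_note_labels(self) -> dict[str, frozenset[str]]:
        """Planted, non-negated subcategories per note (all notes included)."""
        labels: dict[str, set[str]] = {note.note_id: set() for note in self.notes}
        for plant in self.plants:
            if not plant.negated:
                labels[plant.note_id].add(plant.subcategory)
        return {note_id: frozenset(subcats) for note_id, subcats in labels.items()}

    @property
    def gold_admission_profiles(self) -> dict[str, AdmissionProfile]:
        note_to_admission = {n.note_id: n.admission_id for n in self.notes}
        grouped: dict[str, set[str]] = {a.admission_id: set() for a in self.admissions}
        for note_id, labels in self.gold_note_labels.items():
            grouped[note_to_admission[note_id]] |= labels
        return {
            admission_id: AdmissionProfile(admission_id, frozenset(subcats))
            for admission_id, subcats in grouped.items()
        }

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the corpus-module CSV schemas plus gold JSON-lines."""
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "notes": out / "notes.csv",
            "admissions": out / "admissions.csv",
            "gold_notes": out / "gold_note_labels.jsonl",
            "diagnoses": out / "diagnoses.csv",
        }
        corpus_mod.write_notes(self.notes, paths["notes"])
        corpus_mod.write_admissions(self.admissions, paths["admissions"])
        with open(paths["gold_notes"], "w", encoding="utf-8") as handle:
            for note_id, labels in self.gold_note_labels.items():
                handle.write(
                    json.dumps({"note_id": note_id, "subcategories": sorted(labels)})
                    + "\n"
                )
        with open(paths["diagnoses"], "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(["HADM_ID", "ICD_CODE"])
            for admission_id in sorted(self.diagnoses):
                for code in self.diagnoses[admission_id]:
                    writer.writerow([admission_id, code])
        return paths


_TEMPLATE_CACHE: dict | None = None


def load_templates() -> dict:
    """Shipped sentence templates and distractor pool."""
    global _TEMPLATE_CACHE
    if _TEMPLATE_CACHE is None:
        text = resources.files("ineads.data").joinpath("templates.yaml").read_text()
        _TEMPLATE_CACHE = yaml.safe_load(text)
    return _TEMPLATE_CACHE


def held_out_synonyms() -> dict[str, list[str]]:
    """Synonyms deliberately absent from the seed lexicon, per subcategory."""
    text = resources.files("ineads.data").joinpath("held_out_synonyms.tsv").read_text()
    out: dict[str, list[str]] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        out.setdefault(row["subcategory"], []).append(row["synonym"])
    return out


def plantable_vocabulary(lexicon: Lexicon | None = None) -> dict[str, list[str]]:
    """Collision-free plantable terms per subcategory.

    A term is plantable when matching it in isolation yields exactly its own
    subcategory and no other.
    """
    lexicon = lexicon or seed_default_lexicon()
    negation = default_negation_config()
    out: dict[str, list[str]] = {name: [] for name in SUBCATEGORIES}
    for entry in lexicon:
        if not entry.term:
            continue
        probe = Note(
            note_id="probe", patient_id="", admission_id="", category="nursing",
            chart_time=None, text=entry.term,
        )
        annotation = annotate_note(probe, lexicon, negation)
        subcats = {m.subcategory for m in annotation.mentions}
        if subcats == {entry.subcategory}:
            out[entry.subcategory].append(entry.term)
    return out


def _choice(rng: np.random.Generator, options: Mapping[str, float]) -> str:
    names = list(options)
    probs = np.array([options[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    return names[rng.choice(len(names), p=probs)]


def generate_corpus(
    config: GeneratorConfig | None = None,
    lexicon: Lexicon | None = None,
    **overrides,
) -> SyntheticCorpus:
    """Generate a reproducible corpus under the given study conditions."""
    config = replace(config or GeneratorConfig(), **overrides)
    lexicon = lexicon or seed_default_lexicon()
    templates = load_templates()
    plantable = plantable_vocabulary(lexicon)
    forward_triggers = default_negation_config().forward_triggers

    for subcategory, prob in config.plant_probs.items():
        if prob > 0 and not plantable[subcategory]:
            raise ValueError(f"no plantable term for subcategory {subcategory!r}")
        if prob > 0 and not templates["templates"].get(subcategory):
            raise ValueError(f"no template for subcategory {subcategory!r}")

    rng = np.random.default_rng(config.seed)
    n_patients = max(1, int(round(config.n_admissions * 0.85)))
    patient_ids = [f"P{i:06d}" for i in rng.integers(0, n_patients, config.n_admissions)]

    notes: list[Note] = []
    admissions: list[Admission] = []
    plants: list[PlantRecord] = []
    diagnoses: dict[str, list[str]] = {}
    distractor_pool = templates["distractors"]
    note_counter = 0

    for adm_index in range(config.n_admissions):
        admission_id = f"H{adm_index:06d}"
        planted = [
            subcat
            for subcat in sorted(config.plant_probs)
            if rng.random() < config.plant_probs[subcat]
        ]
        n_notes = max(1, int(rng.poisson(config.mean_notes_per_admission)))
        assignment: dict[int, list[str]] = {i: [] for i in range(n_notes)}
        for subcat in planted:
            assignment[int(rng.integers(0, n_notes))].append(subcat)

        n_social = 0
        admission_plants: list[PlantRecord] = []
        for note_index in range(n_notes):
            note_id = f"N{note_counter:07d}"
            note_counter += 1
            sentences: list[tuple[str, PlantRecord | None]] = []
            lo, hi = config.distractors_per_note
            for d in rng.choice(
                len(distractor_pool), size=int(rng.integers(lo, hi + 1)), replace=False
            ):
                sentences.append((distractor_pool[d], None))
            for subcat in assignment[note_index]:
                term = plantable[subcat][int(rng.integers(0, len(plantable[subcat])))]
                template = templates["templates"][subcat][
                    int(rng.integers(0, len(templates["templates"][subcat])))
                ]
                negated = (
                    config.negation_rate > 0
                    and subcat in REDUCED_SUBCATEGORIES
                    and term.split()[0] not in forward_triggers
                    and rng.random() < config.negation_rate
                )
                filler = term
                if negated:
                    trigger = _NEGATION_INSERTS[
                        int(rng.integers(0, len(_NEGATION_INSERTS)))
                    ]
                    filler = f"{trigger} {term}"
                sentence = template.format(term=filler)
                record = PlantRecord(note_id, subcat, term, sentence, negated)
                sentences.append((sentence, record))
            order = rng.permutation(len(sentences))
            text = ". ".join(sentences[i][0] for i in order) + "."
            for i in order:
                if sentences[i][1] is not None:
                    plants.append(sentences[i][1])
                    admission_plants.append(sentences[i][1])
            notes.append(
                Note(
                    note_id=note_id,
                    patient_id=patient_ids[adm_index],
                    admission_id=admission_id,
                    category=_choice(rng, _NOTE_CATEGORIES),
                    chart_time=f"2101-{(adm_index % 12) + 1:02d}-{(note_index % 28) + 1:02d} "
                    f"{8 + (note_index % 12):02d}:00:00",
                    text=text,
                )
            )

        gold_subcats = {p.subcategory for p in admission_plants if not p.negated}
        n_social = len(
            gold_subcats & {s for s in SUBCATEGORIES if SUBCATEGORIES[s].social_elevated}
        )
        age = float(
            np.clip(
                rng.normal(config.age_mean, config.age_sd),
                config.age_bounds[0],
                config.age_bounds[1],
            )
        )
        p_hosp = min(0.95, config.hospital_mortality_base + config.mortality_enrichment * n_social)
        expired_hosp = bool(rng.random() < p_hosp)
        p_follow = min(
            0.95, config.followup_mortality_base + config.mortality_enrichment * n_social
        )
        expired_follow = expired_hosp or bool(rng.random() < p_follow)
        admissions.append(
            Admission(
                admission_id=admission_id,
                patient_id=patient_ids[adm_index],
                age=round(age, 1),
                gender="female" if rng.random() < config.female_p else "male",
                ethnicity=_choice(rng, _ETHNICITIES),
                admission_type=_choice(rng, _ADMISSION_TYPES),
                insurance=_choice(rng, _INSURANCES),
                expired_in_hospital=expired_hosp,
                expired_in_followup=expired_follow,
            )
        )
        codes = [_OTHER_CODES[int(rng.integers(0, len(_OTHER_CODES)))]]
        if rng.random() < config.qualifying_dx_rate:
            codes.append(
                _QUALIFYING_CODES[int(rng.integers(0, len(_QUALIFYING_CODES)))]
            )
        diagnoses[admission_id] = codes

    out = SyntheticCorpus(
        notes=notes,
        admissions=admissions,
        plants=plants,
        diagnoses=diagnoses,
        substitutions=[],
        config=config,
    )
    if config.synonym_substitution_rate > 0:
        out = plant_synonyms(
            out,
            config.synonym_substitution_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return out


def plant_synonyms(
    corpus: SyntheticCorpus,
    rate: float,
    seed: int | None = None,
    synonyms: Mapping[str, Sequence[str]] | None = None,
) -> SyntheticCorpus:
    """Replace planted term surfaces with held-out synonyms at ``rate``.

    The substitute carries the same subcategory, so gold labels are
    unchanged; every substitution is recorded. Plants in subcategories
    without held-out synonyms are left as-is.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    synonyms = synonyms if synonyms is not None else held_out_synonyms()
    if not synonyms:
        raise ValueError("held-out synonym table is empty")
    rng = np.random.default_rng(corpus.config.seed + 1 if seed is None else seed)
    texts = {note.note_id: note.text for note in corpus.notes}
    substitutions: list[Substitution] = []
    new_plants: list[PlantRecord] = []
    for plant in corpus.plants:
        pool = synonyms.get(plant.subcategory, ())
        if pool and rng.random() < rate:
            substitute = pool[int(rng.integers(0, len(pool)))]
            new_sentence = plant.surface.replace(plant.term, substitute, 1)
            texts[plant.note_id] = texts[plant.note_id].replace(
                plant.surface, new_sentence, 1
            )
            substitutions.append(
                Substitution(plant.note_id, plant.subcategory, plant.term, substitute)
            )
            new_plants.append(replace(plant, term=substitute, surface=new_sentence))
        else:
            new_plants.append(plant)
    new_notes = [replace(note, text=texts[note.note_id]) for note in corpus.notes]
    return SyntheticCorpus(
        notes=new_notes,
        admissions=corpus.admissions,
        plants=new_plants,
        diagnoses=corpus.diagnoses,
        substitutions=corpus.substitutions + substitutions,
        config=corpus.config,
    )


def end_to_end_truth(corpus: SyntheticCorpus) -> dict[str, CohortLabel]:
    """Cohort labels computed directly from planted ground truth (no NLP)."""
    return {
        admission_id: classify_ineads(profile)
        for admission_id, profile in corpus.gold_admission_profiles.items()
    }
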