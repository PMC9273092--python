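"""Collocation detection, skip-gram training and the expansion loop."""

import numpy as np
import pytest

from ineads.embedding import (
    ExpansionSession,
    detect_phrases,
    load_model,
    save_model,
    suggest_synonyms,
    train_embedding,
)
from ineads.lexicon import Lexicon, LexiconEntry, seed_default_lexicon


def template_corpus(rng, n=400):
    """Sentences where 'spouse' and 'husband' fill the same slot."""
    frames = [
        ["consent", "signed", "by", "{}", "at", "bedside"],
        ["{}", "phoned", "overnight", "for", "update"],
        ["spoke", "with", "{}", "regarding", "plan"],
    ]
    fillers = ["spouse", "husband", "nurse", "resident"]
    sentences = []
    for _ in range(n):
        frame = frames[rng.integers(0, len(frames))]
        filler = fillers[rng.integers(0, len(fillers))]
        sentences.append([filler if t == "{}" else t for t in frame])
        sentences.append(["vitals", "stable", "afebrile", "overnight"])
    return sentences


class TestDetectPhrases:
    def test_exclusive_pair_merges_others_do_not(self):
        # "palliative care" co-occurs 50x and its components are rare apart;
        # the diverse-context lead-in token stays unmerged.
        fillers = ["rounds", "labs", "meds", "diet", "lines", "drips"]
        sentences = [["start", "palliative", "care", "today"]] * 50 + [
            ["start", filler, "today"] for filler in fillers for _ in range(50)
        ]
        merged = detect_phrases(sentences, min_count=5, threshold=0.2)
        assert ["start", "palliative_care", "today"] in merged
        assert not any("start_" in tok for sent in merged for tok in sent)

    def test_infinite_threshold_changes_nothing(self):
        sentences = [["a", "b"]] * 20
        assert detect_phrases(sentences, threshold=float("inf")) == sentences

    def test_below_min_count_unchanged(self):
        sentences = [["a", "b"]]
        assert detect_phrases(sentences, min_count=5) == sentences

    def test_non_exclusive_pairs_not_merged(self):
        # every pair of promiscuous neighbours stays apart
        sentences = [
            [lead, follow]
            for lead in ("pt", "team", "family")
            for follow in ("stable", "resting", "alert")
            for _ in range(15)
        ]
        assert detect_phrases(sentences) == sentences

    def test_trigram_merges_in_two_passes(self):
        sentences = [["comfort", "focused", "care"]] * 30
        merged = detect_phrases(sentences, max_n=3)
        assert merged == [["comfort_focused_care"]] * 30

    def test_max_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            detect_phrases([], max_n=1)


class TestTrainEmbedding:
    def test_same_seed_identical_vectors(self):
        rng = np.random.default_rng(0)
        sentences = template_corpus(rng, n=100)
        a = train_embedding(sentences, seed=3, epochs=2)
        b = train_embedding(sentences, seed=3, epochs=2)
        assert a.vocabulary == b.vocabulary
        assert np.array_equal(a.vectors, b.vectors)

    def test_slot_sharing_tokens_more_similar_than_random(self):
        rng = np.random.default_rng(1)
        model = train_embedding(template_corpus(rng), seed=5, subsample=0)
        assert model.similarity("spouse", "husband") > model.similarity(
            "spouse", "vitals"
        )

    def test_min_count_filters_vocabulary(self):
        sentences = [["a", "b", "c"]] * 10 + [["rare", "pair"]]
        model = train_embedding(sentences, min_count=5, dim=8, subsample=0)
        assert "rare" not in model and "a" in model

    def test_unreachable_min_count_raises(self):
        with pytest.raises(ValueError, match="min_count"):
            train_embedding([["a", "b"]], min_count=10)

    def test_cosine_self_similarity_and_symmetry(self):
        rng = np.random.default_rng(2)
        model = train_embedding(template_corpus(rng, n=50), seed=1, epochs=2)
        assert model.similarity("spouse", "spouse") == pytest.approx(1.0, abs=1e-6)
        assert model.similarity("spouse", "nurse") == pytest.approx(
            model.similarity("nurse", "spouse"), abs=1e-12
        )

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        model = train_embedding(template_corpus(rng, n=50), seed=1, epochs=2)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.vocabulary == model.vocabulary
        assert np.array_equal(loaded.vectors, model.vectors)
        assert loaded.params == model.params


def _toy_model_and_lexicon():
    """Model over a slot corpus plus a one-subcategory lexicon.

    Subsampling is disabled: the toy corpus is tiny, so every token's
    relative frequency is far above the subsampling threshold.
    """
    rng = np.random.default_rng(4)
    model = train_embedding(template_corpus(rng), seed=6, subsample=0)
    lexicon = Lexicon([LexiconEntry("spouse", "married")])
    return model, lexicon


class TestSuggestSynonyms:
    def test_slot_sharer_is_suggested(self):
        model, lexicon = _toy_model_and_lexicon()
        suggestions = suggest_synonyms(model, lexicon, "married", k=3)
        assert "husband" in [s.candidate_term for s in suggestions]

    def test_k_must_be_positive(self):
        model, lexicon = _toy_model_and_lexicon()
        with pytest.raises(ValueError):
            suggest_synonyms(model, lexicon, "married", k=0)

    def test_no_vocabulary_term_warns_and_returns_empty(self):
        model, _ = _toy_model_and_lexicon()
        lexicon = Lexicon([LexiconEntry("quux", "married")])
        with pytest.warns(UserWarning):
            assert suggest_synonyms(model, lexicon, "married") == []

    def test_all_candidates_in_lexicon_yields_empty(self):
        model, _ = _toy_model_and_lexicon()
        lexicon = Lexicon(
            [LexiconEntry(item.replace("_", " "), "married")
             for item in model.vocabulary]
        )
        assert suggest_synonyms(model, lexicon, "married", k=5) == []

    def test_ranked_by_similarity_descending(self):
        model, lexicon = _toy_model_and_lexicon()
        suggestions = suggest_synonyms(model, lexicon, "married", k=10)
        sims = [s.similarity for s in suggestions]
        assert sims == sorted(sims, reverse=True)


class TestExpansionLoop:
    def test_accept_appends_with_synonym_provenance(self, tmp_path):
        model, lexicon = _toy_model_and_lexicon()
        session = ExpansionSession(model, lexicon, tmp_path / "log.tsv")
        suggestions = session.suggest("married", k=3)
        target = suggestions[0].candidate_term
        session.review("married", suggestions, {target: "accept"})
        entry = [e for e in lexicon if e.term == target]
        assert entry and entry[0].provenance == "accepted_synonym"
        assert (tmp_path / "log.tsv").exists()

    def test_reject_all_terminates_without_growth(self):
        model, lexicon = _toy_model_and_lexicon()
        before = len(lexicon)
        session = ExpansionSession(model, lexicon)
        accepted = session.expand("married", decide=lambda s: False)
        assert accepted == 0 and len(lexicon) == before

    def test_rejected_candidates_never_resurface(self):
        model, lexicon = _toy_model_and_lexicon()
        session = ExpansionSession(model, lexicon)
        first = session.suggest("married", k=3)
        session.review("married", first, {s.candidate_term: "reject" for s in first})
        second = session.suggest("married", k=3)
        assert not ({s.candidate_term for s in first}
                    & {s.candidate_term for s in second})

    def test_decision_for_unknown_candidate_rejected(self):
        model, lexicon = _toy_model_and_lexicon()
        session = ExpansionSession(model, lexicon)
        suggestions = session.suggest("married", k=2)
        with pytest.raises(KeyError):
            session.review("married", suggestions, {"nonexistent": "accept"})

    def test_expansion_grows_monotonically_and_terminates(self):
        model, lexicon = _toy_model_and_lexicon()
        session = ExpansionSession(model, lexicon)
        sizes = [len(lexicon)]
        accepted = session.expand(
            "married", decide=lambda s: s.candidate_term == "husband", k=5
        )
        sizes.append(len(lexicon))
        assert accepted == 1
        assert sizes[1] == sizes[0] + 1


class TestPlantedSynonymRecovery:
    def test_contextual_synonym_reaches_top_k(self):
        """A held-out phrase substituted into seed-term contexts is found."""
        from ineads import GeneratorConfig, SUBCATEGORIES, generate_corpus
        from ineads.corpus import preprocess, sentences_of

        probs = {s: 0.0 for s in SUBCATEGORIES}
        probs["palliative_care"] = 0.6
        probs["hospice"] = 0.6
        corpus = generate_corpus(
            GeneratorConfig(
                n_admissions=250,
                plant_probs=probs,
                synonym_substitution_rate=0.5,
                seed=21,
            )
        )
        sentences = [
            s for note in corpus.notes for s in sentences_of(preprocess(note))
        ]
        model = train_embedding(detect_phrases(sentences), seed=22)
        top = [
            s.candidate_term
            for s in suggest_synonyms(model, seed_default_lexicon(), "hospice", k=10)
        ]
        assert {"respite house", "terminal placement"} & set(top)
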