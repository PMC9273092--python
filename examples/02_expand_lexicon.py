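"""Grow the vocabulary with embedding-based synonym suggestions.

A synthetic corpus plants every subcategory's terms, substituting half of
the plants with held-out synonyms the seed lexicon does not know. Training
a skip-gram model on the corpus and querying a subcategory's terms surfaces
those synonyms for reviewer accept/reject decisions.
"""

from ineads import GeneratorConfig, SUBCATEGORIES, generate_corpus, seed_default_lexicon
from ineads.corpus import preprocess, sentences_of
from ineads.embedding import ExpansionSession, detect_phrases, train_embedding

plant_probs = {name: 0.25 for name in SUBCATEGORIES}
corpus = generate_corpus(
    GeneratorConfig(n_admissions=600, plant_probs=plant_probs,
                    synonym_substitution_rate=0.5, seed=11)
)
print(f"corpus: {len(corpus.notes)} notes, "
      f"{len(corpus.substitutions)} planted synonym substitutions")

sentences = [s for note in corpus.notes for s in sentences_of(preprocess(note))]
model = train_embedding(detect_phrases(sentences), seed=12)
print(f"embedding vocabulary: {len(model.vocabulary)} items "
      f"(multiword expressions merged by collocation detection)\n")

lexicon = seed_default_lexicon()
session = ExpansionSession(model, lexicon)
for subcategory in ("hospice", "palliative_care", "living_alone"):
    print(f"top suggestions for {subcategory}:")
    for s in session.suggest(subcategory, k=4):
        print(f"  {s.candidate_term:24s} cosine {s.similarity:.3f} "
              f"(nearest seed: {s.query_term})")

suggestions = session.suggest("hospice", k=4)
before = len(lexicon)
accepted = session.review(
    "hospice", suggestions, {suggestions[0].candidate_term: "accept"}
)
print(f"\naccepted {accepted[0].candidate_term!r}; "
      f"lexicon grew {before} -> {len(lexicon)} entries "
      f"(provenance=accepted_synonym)")
print("High-cosine candidates are expressions used in the same contexts as")
print("the seed terms — exactly the unseen synonyms the generator planted.")
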