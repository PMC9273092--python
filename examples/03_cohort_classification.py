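"""Classify admissions into possibility / high-likelihood cohorts.

Note annotations are unioned per admission; an admission enters the
"possibility" cohort with >=1 of the five social subcategories indicating
elevated potential, and "high likelihood" with >=4 of the five. Cohort
demographics are then compared against the full cohort.
"""

from ineads import (
    GeneratorConfig,
    annotate_corpus,
    classify_ineads,
    generate_corpus,
    seed_default_lexicon,
)
from ineads.cohort import aggregate_admissions, compare_cohorts, summarize_cohorts

corpus = generate_corpus(GeneratorConfig(n_admissions=1000, seed=5))
annotations, summary = annotate_corpus(corpus.notes, seed_default_lexicon())
print(f"{summary.n_notes_with_subcategory}/{summary.n_notes} notes "
      f"({100 * summary.fraction_with_subcategory:.1f}%) contain >=1 subcategory")

profiles = aggregate_admissions(
    annotations, corpus.notes, [a.admission_id for a in corpus.admissions]
)
labels = {a: classify_ineads(p) for a, p in profiles.items()}
n_possibility = sum(1 for l in labels.values() if l.label != "none")
n_high = sum(1 for l in labels.values() if l.label == "high_likelihood")
print(f"possibility cohort: {n_possibility}/1000 admissions "
      f"({100 * n_possibility / 1000:.1f}%)")
print(f"high-likelihood cohort: {n_high}/1000 admissions")

cohort_summary = summarize_cohorts(corpus.admissions, profiles)
print(f"cohort sizes: {cohort_summary.cohort_n}")

subcohort = [
    a for a in corpus.admissions if labels[a.admission_id].label != "none"
]
tests = compare_cohorts(corpus.admissions, subcohort)
mortality = tests["expired_in_followup"]
print(f"\nfollow-up mortality, possibility vs full cohort: "
      f"chi2={mortality.statistic:.2f}, p={mortality.p_value:.4f}"
      f"{' (p<0.05)' if mortality.significant_05 else ''}")
print("The generator links mortality to the social-subcategory count, so the")
print("possibility cohort shows the elevated mortality the rules should find.")
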