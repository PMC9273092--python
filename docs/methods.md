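# Methods

This note documents the models, rules and numerical choices behind the
package, and what its synthetic-data experiments do and do not show.

## Data model and preprocessing

Notes arrive as a CSV with one row per document (quoted multiline text) and
admissions as a CSV with one row per stay; header names are configurable
with NOTEEVENTS/ADMISSIONS-style defaults. Note categories retained by
default are the document types plausibly carrying social, directive or
capacity content (nursing, physician, discharge summary, social work,
consultation, case management, nutrition, rehabilitation, respiratory,
general); diagnostic report types (radiology, pharmacy, echocardiogram)
are recognised and dropped. Admissions under a configurable minimum age
(default 18 years) are excluded.

Tokenization lowercases, splits on non-alphanumeric runs (keeping intra-word
hyphens, splitting slashes, so `DNR/DNI` → `dnr`, `dni`), removes a shipped
~30-word function-word stopword list, and replaces de-identification spans
`[** ... **]` with a sentinel token. Negation cues (*no, not, denies, ...*)
are never stopwords. Sentence boundaries (`.?!;` and newlines) are recorded
as token indices because the matcher strips the punctuation itself. Lexicon
terms are normalized by the identical pipeline, so "sacrament of the sick"
is stored and matched as `sacrament sick` — one normalization, no
dual-pipeline drift.

## Lexicon

The subcategory schema is fixed: 17 subcategories — 12 surrogate-decision-
maker, 4 advance-directive, 1 decisional-capacity; 11 indicating reduced
and 6 elevated potential; 5 of the elevated ones ("social five": unmarried,
living alone, transitionally situated, surrogate unidentified, advance
directives unavailable) drive the cohort rules, while lacking capacity is
elevated but not social. The shipped seed lexicon holds ~100 terms: the
published sample terms for each subcategory plus curated obvious synonyms,
all tagged `provenance=seed`. Expanded vocabularies load from TSV.

Two encoded ambiguities worth knowing:

* *Code status DNR/DNI* is listed under advance directives **available** —
  whether a DNR mention alone implies an available directive is a domain
  ambiguity; the schema encodes it as listed.
* The same surface form may legitimately belong to two subcategories; the
  validator flags cross-subcategory duplicates as warnings, not errors.

## Matching and negation

Matching is exact on normalized token sequences — recall is grown by
vocabulary expansion, not stemming or fuzzy matching. All maximal matches
are kept, resolved longest-first then leftmost; a token joins at most one
mention per subcategory, while overlap across subcategories is allowed
(nested vocabulary such as "wife" inside "estranged from his wife" is a
real false-positive mechanism, and the pipeline surfaces it rather than
hiding it).

Negation follows the NegEx convention: forward triggers (~15: *no, not,
never, denies, without, unable, cannot, ...*) negate a mention starting
within 6 tokens after them; backward triggers (5: *absent, unlikely,
doubtful, unconfirmed, resolved*) negate within 6 tokens before them; a
sentence boundary or the conjunction *but* breaks the scope. Terms whose
first token is itself a negation trigger (*no living will*, *no contact
from family*, *without caregiver*) carry negation as part of their meaning
and are never flagged. Negated mentions are excluded from a note's label
but retained for audit. Negating a reduced-potential term does **not**
assert its elevated counterpart ("denies married" ≠ unmarried): the
elevated subcategories have their own explicit vocabulary.

## Embedding model and synonym expansion

Sentences (notes split at recorded boundaries) first pass collocation
detection: an adjacent pair merges into one item when its *exclusivity
bond* `count(ab)² / (count(a)·count(b))` — the product of the two
conditional probabilities — reaches 0.2 with at least 5 occurrences,
iterated to trigrams. The bond was chosen over frequency-ratio scores
because it only merges pairs whose components rarely occur apart
("palliative care"), not merely frequent neighbours ("pt reports"); on
template-heavy text, frequency scores merge whole scaffolding phrases and
destroy term boundaries.

The skip-gram model with negative sampling is trained by mini-batch SGD in
numpy: dim 100, window 5, min_count 5, 10 epochs, 5 negatives drawn from
the unigram^0.75 distribution, initial learning rate 0.05 decaying linearly,
frequent-word subsampling at t=1e-3, batch 256 with per-row gradient
averaging (summing collided row updates at full rate diverges), one worker,
one seed — runs are bit-reproducible. Toy corpora a few hundred tokens long
should disable subsampling (`subsample=0`): with so few tokens every word
sits far above the subsampling threshold.

Similarities are computed after removing the vocabulary mean and the top-2
principal components ("all-but-the-top"). Small-corpus skip-gram spaces are
strongly anisotropic — raw cosines saturate near 0.999 for arbitrary pairs
and carry no ranking signal; the correction restores contrast. Self-
similarity remains 1 and symmetry holds.

Suggestion ranks every vocabulary item by its **maximum** cosine to any of
the subcategory's current terms (max-pooling keeps sensitivity to
semantically heterogeneous subcategories), ties broken lexicographically. A
multiword term resolves to its merged phrase item when one exists, else to
an inverse-frequency-weighted mean of its component vectors — the rare
components of a phrase carry its meaning. Candidates already in the
subcategory, previously rejected, or forming a contiguous sub-phrase of an
existing term (fragments offer no new vocabulary) are excluded. The
review loop appends accepted candidates with `accepted_synonym` provenance,
remembers rejections permanently, and terminates when a round accepts
nothing — monotone lexicon growth over a finite vocabulary guarantees
termination.

## Cohort rules and comparisons

An admission's profile is the set union of its notes' non-negated
subcategories; the cohort label is `possibility` when ≥1 of the social five
is present and `high_likelihood` when ≥4 are (admission-level
co-documentation; no within-note requirement), bifurcated by presence of
any reduced-potential subcategory. The label is monotone in the profile.

Cohort characteristics are compared subcohort-vs-full-cohort exactly as
stated — Welch t-test for age, chi-square without continuity correction for
categoricals and mortality. The subcohort is contained in the full cohort,
so these are descriptive comparisons, not independent-sample inference; the
package reports them with that caveat. Gold-standard sampling restricts to
admissions with a qualifying diagnosis code; the shipped pattern list
covers both ICD-9 and ICD-10 forms of psychiatric disorders, tuberculosis,
hepatitis C and HIV/AIDS, since source tables differ in coding era.

## Evaluation

Note-level binary comparison per subcategory: precision TP/(TP+FP)
(positive predictive value), recall TP/(TP+FN) (sensitivity),
F = 2PR/(P+R). The overall row is the unweighted macro mean over
subcategories with any observation (gold or predicted); unobserved ones are
reported as absent and excluded. Documentation frequencies are percentages
of the notes carrying ≥1 gold label, not of all sampled notes. Cohen's
kappa uses the standard marginal chance correction; the degenerate case of
two identical constant labelings (p_e = 1) returns 1.0 with a warning.

## Synthetic corpus generator

The generator emulates the *structure* of a de-identified critical-care
corpus: per admission it samples subcategories by independent Bernoulli
planting, renders each into one note as a telegraphic template sentence
(~5 hand-written templates per subcategory mimicking real note style),
surrounds plants with distractor sentences, samples note categories (70%
nursing / 23% physician), and draws demographics from configurable
marginals (age ~ N(61, 18) truncated to [18, 95], 54% female, published
ethnicity/admission-type/insurance mixes). Mortality is linked to the
number of planted social subcategories (base 9% in-hospital and 43%
follow-up, +10 points per social subcategory), so cohort comparisons have
a real signal to find. Default planting rates use the published
admission-level frequencies for the four best-documented subcategories
(0.72/0.57/0.41/0.36), 0.07 for each of the social five (their independent
union ≈ 30%, the published possibility-cohort share), and modest rates for
the rest. Density is scaled to 3 notes per admission (Poisson, min 1) to
keep thousand-admission experiments fast; the real corpus is denser.

Only *collision-free* terms are planted — terms that, in isolation, match
no other subcategory — so exact recovery is well-defined. Negation, when
enabled, prefixes a reduced-potential plant with a trigger and removes it
from gold. Synonym substitution swaps a plant's surface for a held-out
synonym of the same subcategory (34 synonyms, none known to the seed
lexicon), leaving gold unchanged; every substitution is recorded. Template,
distractor and synonym hygiene (no accidental lexicon matches, no trigger
within scope of a slot) is enforced by tests.

What passing these experiments shows: the pipeline's mechanics — matching,
negation scoping, aggregation, classification, scoring, and the expansion
loop's ability to recover vocabulary that shares contexts with seeds — are
correct. What it does not show: performance on real clinical text, which
has misspellings, section headers, copy-forward, abbreviation overload and
context-dependent negation far beyond trigger windows. The published
validation numbers on real notes (macro F ≈ 0.8) are the realistic
expectation, not the near-perfect figures on synthetic text.

## Numerical and degenerate-input choices

* Percentages are computed as `round(100·k/n)` at the printed precision.
* Chi-square on a characteristic with a single observed level returns
  statistic 0, p 1 (no variation to test) rather than erroring; an all-zero
  table errors.
* Welch t on two zero-variance equal-mean samples reports (0, 1).
* Empty corpora/cohorts yield empty summaries, never division errors;
  `percentage` of an empty cohort raises.
* Matcher determinism: candidate resolution sorts by (length desc, start,
  subcategory, term); mention output by (start, end, subcategory).
* All generator randomness flows from one `numpy` Generator seeded by the
  config; embedding training from its own seed; gold sampling from
  `random.Random(seed)`.

## Problem sizes used by the test suite and acceptance script

Synthetic experiments use 200–2,000 admissions (600 for synonym recovery,
1,000 for noiseless recovery, 2,000 for headline rates), sizes at which the
binomial checks in the tests have comfortable power and the full suite runs
in well under a minute of compute per experiment. These are the package's
fixture scales, chosen once; the generator accepts larger values.

## Known limitations

* Exact matching cannot hit paraphrases the expansion loop has not added.
* Negation handling is trigger-window based; hedges ("family possibly
  unreachable") and family-vs-patient attribution are out of scope.
* The generator's language is template-level; it does not model the
  statistics of real clinical prose.
* The high-likelihood rule under independent planting is an ~10⁻⁴ event, so
  synthetic cohorts rarely populate it; tests exercise it with forced
  planting instead.
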