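"""Admission aggregation, cohort rules, summaries and comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ineads.cohort import (
    AdmissionProfile,
    aggregate_admission,
    aggregate_admissions,
    classify_ineads,
    compare_cohorts,
    percentage,
    sample_gold_standard,
    summarize_cohorts,
)
from ineads.corpus import Admission, Note
from ineads.lexicon import SOCIAL_ELEVATED_FIVE, SUBCATEGORIES
from ineads.matcher import NoteAnnotation, Mention


def _annotation(note_id, subcats):
    mentions = tuple(
        Mention(note_id, s, "t", (0, 1), (0, 1), negated=False) for s in subcats
    )
    return NoteAnnotation(note_id, mentions)


def _admission(admission_id, **overrides):
    base = dict(
        admission_id=admission_id,
        patient_id="p",
        age=60.0,
        gender="female",
        ethnicity="white",
        admission_type="emergency",
        insurance="medicare",
        expired_in_hospital=False,
        expired_in_followup=False,
    )
    base.update(overrides)
    return Admission(**base)


class TestAggregate:
    def test_union_over_notes(self):
        profile = aggregate_admission(
            "h1",
            [_annotation("n1", {"unmarried"}),
             _annotation("n2", {"living_alone", "married"})],
        )
        assert profile.subcategories_present == {"unmarried", "living_alone", "married"}
        assert profile.n_social_elevated == 2
        assert profile.has_reduced

    def test_no_annotated_notes_gives_empty_profile(self):
        profile = aggregate_admission("h1", [])
        assert profile.subcategories_present == frozenset()
        assert profile.n_social_elevated == 0 and not profile.has_reduced

    def test_duplicates_counted_once(self):
        profile = aggregate_admission(
            "h1", [_annotation(f"n{i}", {"hospice"}) for i in range(3)]
        )
        assert profile.subcategories_present == {"hospice"}

    def test_bulk_grouping_requires_known_notes(self):
        notes = [Note("n1", "p", "h1", "nursing", None, "x")]
        with pytest.raises(KeyError):
            aggregate_admissions({"n9": _annotation("n9", set())}, notes)

    def test_bulk_grouping_fills_empty_admissions(self):
        notes = [Note("n1", "p", "h1", "nursing", None, "x")]
        profiles = aggregate_admissions(
            {"n1": _annotation("n1", {"hospice"})}, notes, admission_ids=["h1", "h2"]
        )
        assert profiles["h2"].subcategories_present == frozenset()


class TestClassify:
    def test_four_social_subcategories_is_high_likelihood(self):
        profile = AdmissionProfile(
            "h1",
            frozenset(
                {"unmarried", "living_alone", "transitionally_situated",
                 "surrogate_unidentified"}
            ),
        )
        label = classify_ineads(profile)
        assert label.label == "high_likelihood"
        assert label.bifurcation == "no_reduced_signal"

    def test_lacking_capacity_alone_is_not_social(self):
        label = classify_ineads(AdmissionProfile("h1", frozenset({"lacking_capacity"})))
        assert label.label == "none"

    def test_empty_profile_is_none(self):
        assert classify_ineads(AdmissionProfile("h1", frozenset())).label == "none"

    def test_reduced_signal_bifurcation(self):
        profile = AdmissionProfile(
            "h1", frozenset(SOCIAL_ELEVATED_FIVE | {"married"})
        )
        assert classify_ineads(profile).bifurcation == "has_reduced_signal"

    @given(
        st.sets(st.sampled_from(sorted(SUBCATEGORIES)), max_size=6),
        st.sampled_from(sorted(SUBCATEGORIES)),
    )
    @settings(max_examples=100, deadline=None)
    def test_adding_a_subcategory_never_lowers_the_label(self, subcats, extra):
        order = ["none", "possibility", "high_likelihood"]
        before = classify_ineads(AdmissionProfile("h", frozenset(subcats)))
        after = classify_ineads(AdmissionProfile("h", frozenset(subcats | {extra})))
        assert order.index(after.label) >= order.index(before.label)


class TestPercentage:
    @pytest.mark.parametrize(
        ("count", "total", "ndigits", "expected"),
        [(10772, 23904, 0, 45.0), (7134, 23904, 1, 29.8), (19380, 23904, 0, 81.0)],
    )
    def test_printed_precision(self, count, total, ndigits, expected):
        assert percentage(count, total, ndigits) == expected

    def test_empty_cohort_raises(self):
        with pytest.raises(ZeroDivisionError):
            percentage(1, 0)


class TestSummarize:
    def test_counts_and_empty_cohorts(self):
        admissions = [
            _admission("h1", expired_in_followup=True),
            _admission("h2", gender="male"),
        ]
        profiles = {
            "h1": AdmissionProfile("h1", frozenset({"unmarried"})),
            "h2": AdmissionProfile("h2", frozenset()),
        }
        summary = summarize_cohorts(admissions, profiles)
        assert summary.cohort_n == {"all": 2, "possibility": 1, "high_likelihood": 0}
        table = summary.table
        gender_rows = table[
            (table.cohort == "all") & (table.characteristic == "gender")
        ]
        assert gender_rows.n.sum() == 2
        assert gender_rows.value.sum() == pytest.approx(100.0)

    def test_permutation_invariant(self, small_corpus, lexicon):
        from ineads.matcher import annotate_corpus

        annotations, _ = annotate_corpus(small_corpus.notes, lexicon)
        profiles = aggregate_admissions(
            annotations, small_corpus.notes,
            [a.admission_id for a in small_corpus.admissions],
        )
        forward = summarize_cohorts(small_corpus.admissions, profiles)
        backward = summarize_cohorts(list(reversed(small_corpus.admissions)), profiles)
        assert forward.cohort_n == backward.cohort_n

        def canonical(summary):
            rows = summary.table.round({"value": 9}).values.tolist()
            return sorted(map(tuple, rows))

        assert canonical(forward) == canonical(backward)


class TestCompare:
    def test_identical_cohorts_are_nonsignificant(self):
        cohort = [
            _admission(f"h{i}", gender="male" if i % 2 else "female")
            for i in range(40)
        ]
        results = compare_cohorts(cohort, cohort)
        assert results["gender"].statistic == pytest.approx(0.0)
        assert results["gender"].p_value == pytest.approx(1.0)
        assert not results["gender"].significant_05

    def test_chi_square_matches_hand_calculation(self):
        """50/50 vs 90/10 mortality, n=100 each:
        chi2 = n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 38.095..."""
        full = [
            _admission(f"h{i}", expired_in_followup=i < 50) for i in range(100)
        ]
        sub = [
            _admission(f"h{i}", expired_in_followup=i < 90) for i in range(100)
        ]
        hand = 200 * (50 * 10 - 50 * 90) ** 2 / (100 * 100 * 140 * 60)
        results = compare_cohorts(full, sub)
        assert results["expired_in_followup"].statistic == pytest.approx(hand)
        assert results["expired_in_followup"].significant_001

    def test_equal_age_means_give_t_near_zero(self):
        full = [_admission(f"h{i}", age=50 + (i % 5)) for i in range(50)]
        sub = [_admission(f"h{i}", age=50 + (i % 5)) for i in range(50)]
        assert abs(compare_cohorts(full, sub)["age"].statistic) < 1e-9

    def test_subcohort_must_be_subset(self):
        with pytest.raises(ValueError):
            compare_cohorts([_admission("h1")], [_admission("h9")])

    def test_welch_variant_used(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        full = [_admission(f"h{i}", age=a) for i, a in
                enumerate(rng.normal(60, 20, 80).clip(18, 95))]
        sub = [_admission(f"h{i}", age=full[i].age + 5) for i in range(20)]
        expected = stats.ttest_ind(
            [a.age for a in sub], [a.age for a in full], equal_var=False
        )
        result = compare_cohorts(full, sub)["age"]
        assert result.statistic == pytest.approx(expected.statistic)
        assert result.p_value == pytest.approx(expected.pvalue)


class TestGoldSampling:
    def _notes(self, n=40):
        return [Note(f"n{i}", "p", f"h{i % 20}", "nursing", None, "txt") for i in range(n)]

    def test_reproducible_and_distinct(self):
        notes = self._notes()
        diagnoses = {f"h{i}": ["296.20"] for i in range(20)}
        first = sample_gold_standard(notes, diagnoses, n=10, seed=5)
        second = sample_gold_standard(notes, diagnoses, n=10, seed=5)
        assert [n.note_id for n in first] == [n.note_id for n in second]
        assert len({n.note_id for n in first}) == 10

    def test_different_seeds_differ(self):
        notes = self._notes(400)
        diagnoses = {f"h{i}": ["F32.9"] for i in range(20)}
        a = sample_gold_standard(notes, diagnoses, n=100, seed=1)
        b = sample_gold_standard(notes, diagnoses, n=100, seed=2)
        assert {n.note_id for n in a} != {n.note_id for n in b}

    def test_restricted_to_qualifying_admissions(self):
        notes = self._notes()
        diagnoses = {"h0": ["042"], "h1": ["4019"]}
        sample = sample_gold_standard(notes, diagnoses, n=2, seed=0)
        assert {n.admission_id for n in sample} == {"h0"}

    def test_oversampling_raises(self):
        notes = self._notes()
        diagnoses = {"h0": ["042"]}
        with pytest.raises(ValueError, match="eligible"):
            sample_gold_standard(notes, diagnoses, n=50, seed=0)

    def test_no_qualifying_admissions(self):
        notes = self._notes()
        diagnoses = {"h0": ["4019"]}
        with pytest.raises(ValueError):
            sample_gold_standard(notes, diagnoses, n=1, seed=0)
        assert sample_gold_standard(notes, diagnoses, n=1, seed=0, on_empty="empty") == []
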