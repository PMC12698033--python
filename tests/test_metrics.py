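"""Extraction scoring and outcome score formulas."""

from __future__ import annotations

import random

import pytest

from conftest import INDEX
from oracles import oracle_prf_counts
from trialscreen.metrics import (
    GoldAnnotationSet,
    GoldItem,
    MetricsError,
    checklist_accuracy,
    concept_prf,
    nasa_tlx_score,
    sus_score,
)
from trialscreen.tagger import ConceptAnnotation


def ann(doc_id, start, end, cui="C1", negated=False):
    return ConceptAnnotation(doc_id, start, end, "x" * (end - start), cui,
                             cui, "dsyn", negated, INDEX)


def gold(doc_id, start, end, cui="C1", negated=False):
    return GoldItem(doc_id, start, end, cui, negated)


class TestConceptPrf:
    def test_anticoagulant_style_failure_scores_one_third(self):
        # one true mention detected plus four spurious detections
        predicted = {"d1": [ann("d1", 0, 4), ann("d1", 10, 14),
                            ann("d1", 20, 24), ann("d1", 30, 34),
                            ann("d1", 40, 44)]}
        gold_set = GoldAnnotationSet((gold("d1", 0, 4),))
        row = concept_prf(predicted, gold_set).row("C1")
        assert (row.tp, row.fp, row.fn) == (1, 4, 0)
        assert row.precision == pytest.approx(0.2)
        assert row.recall == pytest.approx(1.0)
        assert row.f1 == pytest.approx(1 / 3)

    def test_exact_agreement_scores_one(self):
        predicted = {"d1": [ann("d1", 0, 4), ann("d1", 10, 14)]}
        gold_set = GoldAnnotationSet((gold("d1", 0, 4), gold("d1", 10, 14)))
        row = concept_prf(predicted, gold_set).row("C1")
        assert row.precision == row.recall == row.f1 == 1.0

    def test_empty_predictions_give_zero_recall(self):
        row = concept_prf({"d1": []},
                          GoldAnnotationSet((gold("d1", 0, 4),))).row("C1")
        assert row.recall == 0.0
        assert row.precision is None  # no predictions -> n/a, not 0 or 1

    def test_negated_prediction_is_not_a_detection(self):
        predicted = {"d1": [ann("d1", 0, 4, negated=True)]}
        row = concept_prf(predicted,
                          GoldAnnotationSet((gold("d1", 0, 4),))).row("C1")
        assert (row.tp, row.fp, row.fn) == (0, 0, 1)

    def test_overlap_policy_accepts_partial_span(self):
        predicted = {"d1": [ann("d1", 2, 6)]}
        gold_set = GoldAnnotationSet((gold("d1", 0, 4),))
        assert concept_prf(predicted, gold_set, "overlap").row("C1").tp == 1
        assert concept_prf(predicted, gold_set, "exact").row("C1").tp == 0

    def test_one_prediction_cannot_absorb_two_gold_mentions(self):
        predicted = {"d1": [ann("d1", 0, 10)]}
        gold_set = GoldAnnotationSet((gold("d1", 0, 4), gold("d1", 6, 10)))
        row = concept_prf(predicted, gold_set).row("C1")
        assert (row.tp, row.fp, row.fn) == (1, 0, 1)

    def test_unknown_doc_id_in_gold_is_an_error(self):
        with pytest.raises(MetricsError, match="unknown doc_id"):
            concept_prf({"d1": []}, GoldAnnotationSet((gold("d9", 0, 4),)))

    def test_matches_exhaustive_matcher_on_random_instances(self):
        rng = random.Random(42)
        for _ in range(150):
            n_pred = rng.randint(0, 6)
            n_gold = rng.randint(0, 6)
            preds = []
            golds = []
            for _ in range(n_pred):
                s = rng.randint(0, 40)
                preds.append(ann("d1", s, s + rng.randint(1, 6)))
            for _ in range(n_gold):
                s = rng.randint(0, 40)
                golds.append(gold("d1", s, s + rng.randint(1, 6)))
            report = concept_prf({"d1": preds}, GoldAnnotationSet(tuple(golds)))
            row = report.row("C1")
            got = (row.tp, row.fp, row.fn) if row else (0, 0, 0)
            want = oracle_prf_counts([p.span for p in preds],
                                     [(g.start, g.end) for g in golds])
            assert got == want

    def test_deleting_lexicon_forms_reduces_recall_exactly(self):
        # plant n affirmed mentions of one concept via the generator, then
        # retag with a lexicon lacking the forms of k of those mentions
        from trialscreen.synth import (GenerationProfile, PlantedFact,
                                       default_lexicon, generate_patient)
        from trialscreen.tagger import (Lexicon, LexiconEntry, SurfaceForm,
                                        annotate_record)

        n = 6
        profile = GenerationProfile(
            seed=1234, n_documents=n, distractor_density=0.0,
            planted_facts=tuple(
                PlantedFact("C0003280", "affirmed", 100.0 + i,
                            "nursing note")
                for i in range(n)))
        bundle = generate_patient(profile)
        full = annotate_record(bundle.record, bundle.lexicon)
        assert concept_prf(full, bundle.gold).row("C0003280").recall == 1.0

        planted_forms = sorted({
            bundle.record.document(g.doc_id).text[g.start:g.end].casefold()
            for g in bundle.gold.items})
        k = 2
        dropped = set(planted_forms[:k])
        n_dropped = sum(
            1 for g in bundle.gold.items
            if bundle.record.document(g.doc_id).text[g.start:g.end]
            .casefold() in dropped)
        entry = bundle.lexicon.entry("C0003280")
        trimmed = Lexicon(tuple(
            e if e.cui != "C0003280" else LexiconEntry(
                e.cui, e.preferred_name, e.semantic_types,
                tuple(f for f in e.surface_forms
                      if f.text.casefold() not in dropped))
            for e in bundle.lexicon.entries))
        partial = annotate_record(bundle.record, trimmed)
        row = concept_prf(partial, bundle.gold).row("C0003280")
        assert row.recall == pytest.approx((n - n_dropped) / n)


class TestChecklistAccuracy:
    def test_ten_of_eleven(self):
        score = checklist_accuracy(["yes"] * 10 + ["no"], ["yes"] * 11)
        assert score.n_correct == 10
        assert score.accuracy == pytest.approx(0.9091, abs=1e-4)

    def test_all_and_none_correct(self):
        assert checklist_accuracy([1, 1], [1, 1]).accuracy == 1.0
        assert checklist_accuracy([0, 0], [1, 1]).accuracy == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(MetricsError, match="mismatch"):
            checklist_accuracy([1], [1, 2])


class TestNasaTlx:
    def test_extremes(self):
        assert nasa_tlx_score([20] * 6, [5, 4, 3, 2, 1, 0]) == 100.0
        assert nasa_tlx_score([0] * 6, [5, 4, 3, 2, 1, 0]) == 0.0

    def test_constant_ratings_invariant_to_weights(self):
        for weights in ([5, 4, 3, 2, 1, 0], [0, 0, 15, 0, 0, 0],
                        [3, 3, 3, 3, 2, 1]):
            assert nasa_tlx_score([10] * 6, weights) == 50.0

    def test_raw_tlx_fallback_without_weights(self):
        assert nasa_tlx_score([10] * 6) == 50.0

    def test_monotone_in_each_rating(self):
        weights = [5, 4, 3, 2, 1, 0]
        base = nasa_tlx_score([10] * 6, weights)
        for i in range(6):
            bumped = [10] * 6
            bumped[i] = 12
            assert nasa_tlx_score(bumped, weights) >= base

    def test_invalid_inputs_rejected(self):
        with pytest.raises(MetricsError):
            nasa_tlx_score([21] + [10] * 5, [5, 4, 3, 2, 1, 0])
        with pytest.raises(MetricsError, match="sum to 15"):
            nasa_tlx_score([10] * 6, [5, 4, 3, 2, 1, 1])


class TestSus:
    def test_best_neutral_worst(self):
        best = [5, 1] * 5   # agree with positive items, reject negative ones
        worst = [1, 5] * 5
        assert sus_score(best) == 100.0
        assert sus_score(worst) == 0.0
        assert sus_score([3] * 10) == 50.0

    def test_monotone_direction_depends_on_item_parity(self):
        base = sus_score([3] * 10)
        for i in range(10):
            bumped = [3] * 10
            bumped[i] = 4
            if i % 2 == 0:  # odd-numbered item (1-based): positive wording
                assert sus_score(bumped) > base
            else:
                assert sus_score(bumped) < base

    def test_invalid_inputs_rejected(self):
        with pytest.raises(MetricsError):
            sus_score([3] * 9)
        with pytest.raises(MetricsError):
            sus_score([3] * 9 + [6])
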