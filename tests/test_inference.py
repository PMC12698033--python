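"""Three-valued criterion evaluation: leaves, combinators, screening."""

from __future__ import annotations

import random
from datetime import timedelta

import pytest

from conftest import INDEX, make_doc, make_lab, make_record
from oracles import oracle_eval
from randgen import random_expr, random_patient
from trialscreen.inference import (
    Status,
    eval_concept_criterion,
    eval_expr,
    eval_lab_criterion,
    kleene_and,
    kleene_not,
    kleene_or,
    screen_patient,
)
from trialscreen.rules import (
    Checklist,
    ChecklistItem,
    Comparator,
    ConceptCriterion,
    ConceptRef,
    Direction,
    LabCriterion,
    LabItem,
    LabMode,
    Role,
    RuleExpr,
    TemporalWindow,
    TimeUnit,
)
from trialscreen.tagger import ConceptAnnotation

D7 = TemporalWindow(7, TimeUnit.DAYS, Direction.BEFORE_INDEX)
Y3 = TemporalWindow(3, TimeUnit.YEARS, Direction.BEFORE_INDEX)


def lab_crit(code="PLT", cmp=Comparator.LT, threshold=100_000.0,
             mode=LabMode.ABSOLUTE, window=None):
    return LabCriterion("c1", LabItem(code), cmp, threshold, "", mode, window)


def concept_crit(cuis=("C1",), doc_types=("outpatient note",), window=None):
    return ConceptCriterion(
        "c1", tuple(ConceptRef(c, c) for c in cuis),
        frozenset(doc_types), window)


def ann(doc_id, cui="C1", negated=False, ts=INDEX, start=0, end=4):
    return ConceptAnnotation(doc_id, start, end, "xxxx", cui, cui, "dsyn",
                             negated, ts)


class TestLabCriterion:
    def test_value_below_threshold_is_met_with_evidence(self):
        record = make_record(labs=[make_lab("PLT", 95_000.0)])
        v = eval_lab_criterion(lab_crit(), record)
        assert v.status is Status.MET
        assert len(v.evidence) == 1
        assert v.evidence[0].value == 95_000.0

    def test_ratio_boundary_value_met_under_le(self):
        record = make_record(labs=[
            make_lab("APTT", 42.0, 30.0, INDEX - timedelta(days=3))])
        crit = lab_crit("APTT", Comparator.LE, 1.4,
                        LabMode.RATIO_TO_CONTROL, D7)
        v = eval_lab_criterion(crit, record)
        assert v.status is Status.MET  # 42/30 == 1.4 exactly

    def test_no_in_window_result_is_unknown(self):
        record = make_record(labs=[
            make_lab("APTT", 42.0, 30.0, INDEX - timedelta(days=10))])
        crit = lab_crit("APTT", Comparator.LE, 1.4,
                        LabMode.RATIO_TO_CONTROL, D7)
        v = eval_lab_criterion(crit, record)
        assert v.status is Status.UNKNOWN
        assert v.evidence == ()

    def test_missing_control_in_ratio_mode_is_unknown_with_explanation(self):
        record = make_record(labs=[make_lab("APTT", 42.0, None)])
        crit = lab_crit("APTT", Comparator.LE, 1.4, LabMode.RATIO_TO_CONTROL)
        v = eval_lab_criterion(crit, record)
        assert v.status is Status.UNKNOWN
        assert "control" in v.explanation


class TestConceptCriterion:
    def test_affirmed_in_window_mention_is_met(self):
        doc = make_doc("d1", "outpatient note", INDEX - timedelta(days=730))
        record = make_record([doc])
        v = eval_concept_criterion(concept_crit(window=Y3), record,
                                   {"d1": [ann("d1", ts=doc.timestamp)]})
        assert v.status is Status.MET
        assert v.evidence[0].doc_id == "d1"

    def test_only_negated_mentions_is_not_met_without_evidence(self):
        doc = make_doc("d1", "outpatient note")
        record = make_record([doc])
        v = eval_concept_criterion(concept_crit(), record,
                                   {"d1": [ann("d1", negated=True)]})
        assert v.status is Status.NOT_MET
        assert v.evidence == ()

    def test_mention_outside_window_is_not_met(self):
        doc = make_doc("d1", "outpatient note",
                       INDEX - timedelta(days=4 * 365))
        record = make_record([doc])
        v = eval_concept_criterion(concept_crit(window=Y3), record,
                                   {"d1": [ann("d1", ts=doc.timestamp)]})
        assert v.status is Status.NOT_MET

    def test_no_documents_of_requested_type_is_unknown(self):
        record = make_record([make_doc("d1", "nursing note")])
        v = eval_concept_criterion(concept_crit(), record, {"d1": []})
        assert v.status is Status.UNKNOWN

    def test_adding_affirmed_mention_is_monotone(self):
        doc1 = make_doc("d1", "outpatient note")
        record1 = make_record([doc1])
        anns = {"d1": [ann("d1")]}
        before = eval_concept_criterion(concept_crit(), record1, anns)
        doc2 = make_doc("d2", "outpatient note")
        record2 = make_record([doc1, doc2])
        anns2 = {"d1": [ann("d1")], "d2": [ann("d2")]}
        after = eval_concept_criterion(concept_crit(), record2, anns2)
        assert before.status is Status.MET
        assert after.status is Status.MET


class TestKleene:
    S = (Status.MET, Status.NOT_MET, Status.UNKNOWN)

    def test_and_table(self):
        assert kleene_and([Status.MET, Status.MET]) is Status.MET
        assert kleene_and([Status.MET, Status.UNKNOWN]) is Status.UNKNOWN
        assert kleene_and([Status.UNKNOWN, Status.NOT_MET]) is Status.NOT_MET

    def test_or_table(self):
        assert kleene_or([Status.UNKNOWN, Status.MET]) is Status.MET
        assert kleene_or([Status.NOT_MET, Status.NOT_MET]) is Status.NOT_MET
        assert kleene_or([Status.NOT_MET, Status.UNKNOWN]) is Status.UNKNOWN

    def test_double_negation(self):
        for s in self.S:
            assert kleene_not(kleene_not(s)) is s

    def test_de_morgan_over_all_pairs(self):
        for a in self.S:
            for b in self.S:
                assert kleene_not(kleene_and([a, b])) is \
                    kleene_or([kleene_not(a), kleene_not(b)])
                assert kleene_not(kleene_or([a, b])) is \
                    kleene_and([kleene_not(a), kleene_not(b)])


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_small_patients(self):
        rng = random.Random(20240601)
        for _ in range(400):
            record, annotations = random_patient(rng)
            expr = random_expr(rng, depth=rng.randint(0, 4))
            got = eval_expr(expr, record, annotations).status
            want = oracle_eval(expr, record, annotations)
            assert got is want, f"{expr} -> {got} vs oracle {want}"

    def test_evidence_resolves_into_record(self):
        rng = random.Random(77)
        for _ in range(100):
            record, annotations = random_patient(rng)
            expr = random_expr(rng, depth=3)
            v = eval_expr(expr, record, annotations)
            doc_ids = {d.doc_id for d in record.documents}
            lab_codes = {l.item.code for l in record.labs}
            for ev in v.evidence:
                if hasattr(ev, "doc_id"):
                    assert ev.doc_id in doc_ids
                else:
                    assert ev.item_code in lab_codes

    def test_met_leaves_always_carry_evidence(self):
        rng = random.Random(33)
        checked = 0
        for _ in range(200):
            record, annotations = random_patient(rng)
            expr = random_expr(rng, depth=0)
            v = eval_expr(expr, record, annotations)
            if v.status is Status.MET:
                checked += 1
                assert v.evidence
        assert checked > 10  # the property was actually exercised


class TestScreenPatient:
    def test_verdict_order_matches_items_and_relevant_docs_subset(self):
        doc = make_doc("d1", "outpatient note")
        record = make_record([doc], [make_lab("PLT", 95_000.0)])
        checklist = Checklist("t", "1", (
            ChecklistItem("platelets", Role.EXCLUSION,
                          RuleExpr.lab(lab_crit())),
            ChecklistItem("history", Role.EXCLUSION,
                          RuleExpr.concept(concept_crit())),
        ))
        result = screen_patient(checklist, record, {"d1": [ann("d1")]})
        assert [v.criterion_label for v in result.verdicts] == \
            ["platelets", "history"]
        assert result.relevant_docs == {"d1"}

    def test_generated_patient_matches_planted_expectations(self):
        from trialscreen.synth import GenerationProfile, generate_patient
        from trialscreen.tagger import annotate_record

        bundle = generate_patient(GenerationProfile(seed=21, n_documents=10))
        anns = annotate_record(bundle.record, bundle.lexicon)
        result = screen_patient(bundle.checklist, bundle.record, anns)
        assert tuple(v.status for v in result.verdicts) == \
            bundle.expected_verdicts
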