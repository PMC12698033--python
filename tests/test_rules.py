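"""Rule model: validation, serialization round-trips, DSL parsing."""

from __future__ import annotations

import random
from dataclasses import replace

import pytest

from randgen import random_checklist
from trialscreen.dsl import DslError, parse_dsl, pretty_print
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
    NodeKind,
    Role,
    RuleExpr,
    RuleFileError,
    TemporalWindow,
    TimeUnit,
    deserialize,
    serialize,
    validate_checklist,
    validate_expr,
)


def lab_leaf(**kw):
    defaults = dict(criterion_id="c1", item=LabItem("PLT"),
                    comparator=Comparator.LT, threshold=100_000.0)
    defaults.update(kw)
    return RuleExpr.lab(LabCriterion(**defaults))


def concept_leaf(**kw):
    defaults = dict(criterion_id="c1",
                    concepts=(ConceptRef("C1", "Headache"),),
                    doc_types=frozenset({"outpatient note"}))
    defaults.update(kw)
    return RuleExpr.concept(ConceptCriterion(**defaults))


class TestValidation:
    def test_well_formed_tree_yields_empty_report(self):
        expr = RuleExpr.or_(concept_leaf(),
                            RuleExpr.and_(lab_leaf(),
                                          RuleExpr.not_(concept_leaf())))
        assert validate_expr(expr) == []

    @pytest.mark.parametrize("expr,needle", [
        (RuleExpr(NodeKind.AND, children=(lab_leaf(),)), "AND requires >= 2"),
        (RuleExpr(NodeKind.OR, children=(lab_leaf(),)), "OR requires >= 2"),
        (RuleExpr(NodeKind.NOT, children=(lab_leaf(), lab_leaf())),
         "NOT requires exactly 1"),
        (lab_leaf(threshold=float("inf")), "finite"),
        (lab_leaf(threshold=-1.0, mode=LabMode.RATIO_TO_CONTROL), "> 0"),
        (concept_leaf(concepts=()), ">= 1 concept"),
        (concept_leaf(doc_types=frozenset()), "doc_types"),
        (concept_leaf(concepts=(ConceptRef("C1", "a"), ConceptRef("C1", "b"))),
         "unique"),
        (concept_leaf(window=TemporalWindow(0, TimeUnit.DAYS,
                                            Direction.BEFORE_INDEX)),
         "window amount"),
    ])
    def test_single_invariant_mutations_are_caught(self, expr, needle):
        violations = validate_expr(expr)
        assert violations, "expected a violation"
        assert any(needle in v.message for v in violations)

    def test_violation_names_offending_node_path(self):
        bad = RuleExpr.and_(lab_leaf(),
                            RuleExpr(NodeKind.AND, children=(lab_leaf(),)))
        violations = validate_expr(bad)
        assert [v.path for v in violations] == ["$.1"]

    def test_checklist_duplicate_labels_rejected(self):
        item = ChecklistItem("dup", Role.INCLUSION, lab_leaf())
        violations = validate_checklist(
            Checklist("t", "1", (item, item)))
        assert any("unique" in v.message for v in violations)


class TestSerialization:
    def test_round_trip_identity_over_generated_checklists(self):
        rng = random.Random(20240615)
        for _ in range(200):
            checklist = random_checklist(rng)
            assert deserialize(serialize(checklist)) == checklist

    def test_reserialization_is_byte_identical(self):
        rng = random.Random(5)
        checklist = random_checklist(rng)
        data = serialize(checklist)
        assert serialize(deserialize(data)) == data

    def test_unknown_schema_version_rejected(self):
        data = serialize(Checklist("t", "1", (ChecklistItem(
            "a", Role.INCLUSION, lab_leaf()),)))
        tampered = data.replace(b'"schema_version": "1"',
                                b'"schema_version": "99"')
        with pytest.raises(RuleFileError, match="unknown schema version"):
            deserialize(tampered)

    def test_unknown_fields_rejected_not_ignored(self):
        data = serialize(Checklist("t", "1", (ChecklistItem(
            "a", Role.INCLUSION, lab_leaf()),)))
        tampered = data.replace(b'"trial_name"', b'"surprise": 1, "trial_name"')
        with pytest.raises(RuleFileError, match="unknown field"):
            deserialize(tampered)

    def test_malformed_document_rejected(self):
        with pytest.raises(RuleFileError, match="malformed"):
            deserialize(b"{not json")

    def test_eleven_item_fixture_survives_round_trip(self, checklist):
        assert len(checklist.items) == 11
        assert deserialize(serialize(checklist)) == checklist


class TestDsl:
    def test_platelet_example(self):
        cl = parse_dsl('checklist "t" version "1"\n'
                       'exclude "low platelets": lab "Platelets" < 100000\n')
        crit = cl.items[0].expr.payload
        assert cl.items[0].role is Role.EXCLUSION
        assert crit.comparator is Comparator.LT
        assert crit.threshold == 100_000
        assert crit.mode is LabMode.ABSOLUTE
        assert crit.window is None

    def test_ratio_to_control_with_window(self):
        cl = parse_dsl(
            'checklist "t" version "1"\n'
            'include "aptt": lab "APTT" <= 1.4 x control '
            'within 7 days before index\n')
        crit = cl.items[0].expr.payload
        assert crit.comparator is Comparator.LE
        assert crit.threshold == pytest.approx(1.4)
        assert crit.mode is LabMode.RATIO_TO_CONTROL
        assert crit.window == TemporalWindow(7, TimeUnit.DAYS,
                                             Direction.BEFORE_INDEX)

    def test_disjunction_of_concept_criteria(self):
        cl = parse_dsl(
            'checklist "t" version "1"\n'
            'exclude "history": '
            '(concept "Headache" in [outpatient, admission] '
            'within 3 years before index) '
            'or (concept "Head injury" in [outpatient, admission] '
            'within 3 years before index)\n')
        expr = cl.items[0].expr
        assert expr.kind is NodeKind.OR
        assert len(expr.children) == 2
        for child in expr.children:
            assert child.kind is NodeKind.CONCEPT
            assert child.payload.doc_types == frozenset({"outpatient",
                                                         "admission"})
            assert child.payload.window.unit is TimeUnit.YEARS

    def test_syntax_error_carries_position(self):
        with pytest.raises(DslError) as exc:
            parse_dsl('checklist "t" version "1"\n'
                      'include "x": lab "PLT" ! 5\n')
        assert exc.value.line == 2
        assert exc.value.column > 0

    def test_unresolved_concept_name_is_an_error(self, lexicon):
        with pytest.raises(DslError, match="not found in lexicon"):
            parse_dsl('checklist "t" version "1"\n'
                      'include "x": concept "Teleportation" in [admission]\n',
                      lexicon=lexicon)

    def test_concept_resolution_via_surface_form(self, lexicon):
        cl = parse_dsl('checklist "t" version "1"\n'
                       'include "x": concept "warfarin" in [admission note]\n',
                       lexicon=lexicon)
        ref = cl.items[0].expr.payload.concepts[0]
        assert ref.cui == "C0003280"
        assert ref.preferred_name == "Anticoagulant"

    def test_undeclared_lab_item_is_an_error(self):
        with pytest.raises(DslError, match="undeclared lab item"):
            parse_dsl('checklist "t" version "1"\n'
                      'include "x": lab "XYZ" < 5\n',
                      known_lab_items=["PLT", "APTT"])

    def test_empty_checklist_rejected(self):
        with pytest.raises(DslError, match="no items"):
            parse_dsl('checklist "t" version "1"\n')

    def test_pretty_print_parse_identity_over_generated_checklists(self):
        rng = random.Random(987)
        for _ in range(200):
            checklist = random_checklist(rng)
            assert parse_dsl(pretty_print(checklist)) == checklist

    def test_pretty_print_quotes_awkward_strings(self):
        cl = Checklist('tr"ial\\', "1", (ChecklistItem(
            'label "quoted"', Role.INCLUSION,
            concept_leaf(criterion_id="i1.c1",
                         doc_types=frozenset({"weird  type", "not"}))),))
        assert parse_dsl(pretty_print(cl)) == cl
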