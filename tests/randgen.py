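"""Seeded random generators for property-style tests.

Generates valid checklists (with the canonical positional criterion-id
scheme the DSL parser uses, so pretty-print/parse identity is testable),
random rule expressions over a small vocabulary, and small random
patients with directly synthesized annotations — no tagger involved, so
oracle-equivalence tests exercise the inference engine in isolation.
"""

from __future__ import annotations

import random
from datetime import datetime, timedelta

from trialscreen.emr import ClinicalDocument, LabResult, PatientRecord
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

INDEX = datetime(2024, 6, 15, 9, 30)

LAB_CODES = ("PLT", "APTT", "GLU", "INR")
CUIS = ("C001", "C002", "C003", "C004")
DOC_TYPES = ("admission note", "outpatient note", "discharge summary",
             "nursing note")


def random_window(rng: random.Random, allow_none=True):
    if allow_none and rng.random() < 0.4:
        return None
    return TemporalWindow(
        amount=rng.randint(1, 40),
        unit=rng.choice(list(TimeUnit)),
        direction=(Direction.BEFORE_INDEX if rng.random() < 0.8
                   else Direction.AFTER_INDEX),
    )


def random_lab_criterion(rng: random.Random, criterion_id: str) -> LabCriterion:
    mode = LabMode.RATIO_TO_CONTROL if rng.random() < 0.3 else LabMode.ABSOLUTE
    if mode is LabMode.RATIO_TO_CONTROL:
        threshold = round(rng.uniform(0.5, 3.0), 2)
    else:
        threshold = round(rng.uniform(-50.0, 400.0), 1)
    return LabCriterion(
        criterion_id=criterion_id,
        item=LabItem(code=rng.choice(LAB_CODES)),
        comparator=rng.choice(list(Comparator)),
        threshold=threshold,
        unit=rng.choice(("", "mg/dL", "s")),
        mode=mode,
        window=random_window(rng),
    )


def random_concept_criterion(rng: random.Random,
                             criterion_id: str) -> ConceptCriterion:
    cuis = rng.sample(CUIS, k=rng.randint(1, 3))
    return ConceptCriterion(
        criterion_id=criterion_id,
        concepts=tuple(ConceptRef(cui=c, preferred_name=c) for c in cuis),
        doc_types=frozenset(rng.sample(DOC_TYPES, k=rng.randint(1, 3))),
        window=random_window(rng),
    )


def random_expr(rng: random.Random, depth: int,
                ids: list[int] | None = None, item_no: int = 1) -> RuleExpr:
    """Random expression of depth <= ``depth`` with canonical leaf ids."""
    if ids is None:
        ids = [0]

    def next_id() -> str:
        ids[0] += 1
        return f"i{item_no}.c{ids[0]}"

    if depth <= 0 or rng.random() < 0.35:
        if rng.random() < 0.5:
            return RuleExpr.lab(random_lab_criterion(rng, next_id()))
        return RuleExpr.concept(random_concept_criterion(rng, next_id()))
    kind = rng.random()
    if kind < 0.4:
        n = rng.randint(2, 3)
        return RuleExpr.and_(*(random_expr(rng, depth - 1, ids, item_no)
                               for _ in range(n)))
    if kind < 0.8:
        n = rng.randint(2, 3)
        return RuleExpr.or_(*(random_expr(rng, depth - 1, ids, item_no)
                              for _ in range(n)))
    return RuleExpr.not_(random_expr(rng, depth - 1, ids, item_no))


def random_checklist(rng: random.Random, max_items: int = 5) -> Checklist:
    n = rng.randint(1, max_items)
    items = tuple(
        ChecklistItem(
            label=f"criterion {i + 1}",
            role=rng.choice(list(Role)),
            expr=random_expr(rng, depth=rng.randint(0, 3), ids=[0],
                             item_no=i + 1),
        )
        for i in range(n)
    )
    return Checklist(trial_name=f"trial-{rng.randint(1, 999)}",
                     version=f"{rng.randint(0, 9)}.{rng.randint(0, 9)}",
                     items=items)


def random_patient(rng: random.Random, max_docs: int = 8, max_labs: int = 8
                   ) -> tuple[PatientRecord, dict[str, list[ConceptAnnotation]]]:
    """Small random patient plus directly synthesized annotations."""
    n_docs = rng.randint(0, max_docs)
    documents = []
    annotations: dict[str, list[ConceptAnnotation]] = {}
    for i in range(n_docs):
        doc_id = f"d{i + 1}"
        # timestamps straddle the index so AFTER windows get exercised
        ts = INDEX + timedelta(days=rng.uniform(-1500.0, 100.0))
        text = "x" * 80
        doc = ClinicalDocument(doc_id, rng.choice(DOC_TYPES), ts, text)
        documents.append(doc)
        anns = []
        for j in range(rng.randint(0, 3)):
            start = rng.randint(0, 70)
            end = start + rng.randint(1, 8)
            anns.append(ConceptAnnotation(
                doc_id=doc_id, start=start, end=end,
                matched_text=text[start:end],
                cui=rng.choice(CUIS), preferred_name="c",
                semantic_type="dsyn",
                negated=rng.random() < 0.3,
                doc_timestamp=ts,
            ))
        annotations[doc_id] = anns
    labs = []
    for _ in range(rng.randint(0, max_labs)):
        # coarse timestamps make latest-lab timestamp ties reachable
        ts = INDEX - timedelta(days=rng.randint(0, 45))
        labs.append(LabResult(
            item=LabItem(code=rng.choice(LAB_CODES)),
            value=round(rng.uniform(-10.0, 400.0), 1),
            unit="",
            control_value=None if rng.random() < 0.4
            else round(rng.uniform(10.0, 40.0), 1),
            timestamp=ts,
        ))
    record = PatientRecord(patient_id="PX", index_time=INDEX,
                           documents=tuple(documents), labs=tuple(labs))
    return record, annotations
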