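"""Three-valued criterion evaluation over records and annotations.

Each checklist criterion is answered MET, NOT_MET, or UNKNOWN, with the
evidence (lab rows or concept mentions) that produced the answer.
Verdicts answer the criterion *as written*: an exclusion criterion that
the patient satisfies is reported MET; no polarity flipping happens in
the engine — the report states the role next to the status.

Missing data is epistemically distinct from a negative finding, so it is
never silently coerced to "no":

* a lab criterion with no in-window result (or a ratio criterion whose
  latest result lacks a control value) is UNKNOWN;
* a concept criterion is NOT_MET when the requested document types exist
  but hold no qualifying affirmed mention (closed-world at the leaf),
  and UNKNOWN only when the record has no document of the requested
  types at all.

Combinators use strong-Kleene three-valued logic: AND is MET iff every
child is MET and NOT_MET iff any child is NOT_MET; OR is the dual; NOT
swaps MET and NOT_MET and fixes UNKNOWN.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

from .emr import PatientRecord, in_window, latest_lab
from .rules import (
    Checklist,
    ConceptCriterion,
    LabCriterion,
    LabMode,
    NodeKind,
    Role,
    RuleExpr,
)
from .tagger import ConceptAnnotation


class Status(str, enum.Enum):
    MET = "MET"
    NOT_MET = "NOT_MET"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class LabEvidence:
    item_code: str
    value: float
    unit: str
    control_value: Optional[float]
    timestamp: str  # ISO-8601


@dataclass(frozen=True)
class AnnotationEvidence:
    doc_id: str
    start: int
    end: int
    cui: str
    matched_text: str


Evidence = Union[LabEvidence, AnnotationEvidence]


@dataclass(frozen=True)
class CriterionVerdict:
    criterion_label: str
    role: Role
    status: Status
    evidence: tuple[Evidence, ...]
    explanation: str


@dataclass(frozen=True)
class ScreeningResult:
    patient_id: str
    trial_name: str
    checklist_version: str
    verdicts: tuple[CriterionVerdict, ...]
    relevant_docs: frozenset[str]


# ---------------------------------------------------------------------------
# Leaf evaluation
# ---------------------------------------------------------------------------

def _window_phrase(window) -> str:
    if window is None:
        return "any time"
    return (f"within {window.amount} {window.unit.value.lower()} "
            f"{'before' if window.direction.value == 'BEFORE_INDEX' else 'after'}"
            f" index")


def eval_lab_criterion(crit: LabCriterion, record: PatientRecord,
                       label: str = "", role: Role = Role.INCLUSION
                       ) -> CriterionVerdict:
    """Evaluate a numeric lab criterion against the latest in-window result."""
    result = latest_lab(record, crit.item.code, crit.window)
    where = _window_phrase(crit.window)
    if result is None:
        return CriterionVerdict(
            label, role, Status.UNKNOWN, (),
            f"no {crit.item.display} result {where}")
    if crit.mode is LabMode.RATIO_TO_CONTROL:
        if result.control_value is None:
            return CriterionVerdict(
                label, role, Status.UNKNOWN, (),
                f"{crit.item.display} at {result.timestamp.isoformat()} "
                f"has no control value for ratio comparison")
        observed = result.value / result.control_value
        descr = (f"{crit.item.display} ratio {observed:g} "
                 f"({result.value:g}/{result.control_value:g})")
    else:
        observed = result.value
        descr = f"{crit.item.display} {observed:g}"
    holds = crit.comparator.apply(observed, crit.threshold)
    status = Status.MET if holds else Status.NOT_MET
    ev = LabEvidence(
        item_code=crit.item.code,
        value=result.value,
        unit=result.unit,
        control_value=result.control_value,
        timestamp=result.timestamp.isoformat(),
    )
    verdict_word = "satisfies" if holds else "fails"
    return CriterionVerdict(
        label, role, status, (ev,),
        f"{descr} {verdict_word} {crit.comparator.symbol} "
        f"{crit.threshold:g}{' x control' if crit.mode is LabMode.RATIO_TO_CONTROL else ''}")


def eval_concept_criterion(crit: ConceptCriterion, record: PatientRecord,
                           annotations: Mapping[str, Sequence[ConceptAnnotation]],
                           label: str = "", role: Role = Role.INCLUSION
                           ) -> CriterionVerdict:
    """Evaluate a concept criterion against extracted annotations.

    MET iff at least one non-negated mention of one of the criterion's
    concepts occurs in a document of the requested types whose timestamp
    lies in the window; all qualifying mentions are cited as evidence.
    """
    wanted_cuis = {c.cui for c in crit.concepts}
    docs_of_type = [d for d in record.documents if d.doc_type in crit.doc_types]
    names = " or ".join(c.preferred_name for c in crit.concepts)
    where = _window_phrase(crit.window)
    if not docs_of_type:
        return CriterionVerdict(
            label, role, Status.UNKNOWN, (),
            f"record has no documents of type(s) "
            f"{', '.join(sorted(crit.doc_types))}")
    hits: list[AnnotationEvidence] = []
    for doc in docs_of_type:
        if not in_window(doc.timestamp, crit.window, record.index_time):
            continue
        for ann in annotations.get(doc.doc_id, ()):
            if ann.negated or ann.cui not in wanted_cuis:
                continue
            hits.append(AnnotationEvidence(
                doc_id=doc.doc_id, start=ann.start, end=ann.end,
                cui=ann.cui, matched_text=ann.matched_text))
    if hits:
        return CriterionVerdict(
            label, role, Status.MET, tuple(hits),
            f"{len(hits)} affirmed mention(s) of {names} {where} in "
            f"{len({h.doc_id for h in hits})} document(s)")
    return CriterionVerdict(
        label, role, Status.NOT_MET, (),
        f"no affirmed mention of {names} {where} in "
        f"{', '.join(sorted(crit.doc_types))} documents")


# ---------------------------------------------------------------------------
# Combinators (strong Kleene)
# ---------------------------------------------------------------------------

def kleene_and(statuses: Sequence[Status]) -> Status:
    if any(s is Status.NOT_MET for s in statuses):
        return Status.NOT_MET
    if all(s is Status.MET for s in statuses):
        return Status.MET
    return Status.UNKNOWN


def kleene_or(statuses: Sequence[Status]) -> Status:
    if any(s is Status.MET for s in statuses):
        return Status.MET
    if all(s is Status.NOT_MET for s in statuses):
        return Status.NOT_MET
    return Status.UNKNOWN


def kleene_not(status: Status) -> Status:
    if status is Status.MET:
        return Status.NOT_MET
    if status is Status.NOT_MET:
        return Status.MET
    return Status.UNKNOWN


def eval_expr(expr: RuleExpr, record: PatientRecord,
              annotations: Mapping[str, Sequence[ConceptAnnotation]],
              label: str = "", role: Role = Role.INCLUSION) -> CriterionVerdict:
    """Evaluate a rule-expression tree to a single verdict.

    Evidence of a combinator is the union of evidence from the children
    whose status determined the outcome (MET children of a MET AND/OR,
    NOT_MET children of a NOT_MET AND/OR).
    """
    if expr.kind is NodeKind.LAB:
        return eval_lab_criterion(expr.payload, record, label, role)
    if expr.kind is NodeKind.CONCEPT:
        return eval_concept_criterion(expr.payload, record, annotations,
                                      label, role)
    child_verdicts = [eval_expr(ch, record, annotations, label, role)
                      for ch in expr.children]
    statuses = [v.status for v in child_verdicts]
    if expr.kind is NodeKind.NOT:
        inner = child_verdicts[0]
        return CriterionVerdict(
            label, role, kleene_not(inner.status), inner.evidence,
            f"not({inner.explanation})")
    if expr.kind is NodeKind.AND:
        status = kleene_and(statuses)
        word = "and"
    else:
        status = kleene_or(statuses)
        word = "or"
    if status is Status.MET:
        contributing = [v for v in child_verdicts if v.status is Status.MET]
    elif status is Status.NOT_MET:
        contributing = [v for v in child_verdicts if v.status is Status.NOT_MET]
    else:
        contributing = []
    evidence: list = []
    for v in contributing:
        for ev in v.evidence:
            if ev not in evidence:
                evidence.append(ev)
    explanation = f" {word} ".join(f"[{v.status.value}: {v.explanation}]"
                                   for v in child_verdicts)
    return CriterionVerdict(label, role, status, tuple(evidence), explanation)


def screen_patient(checklist: Checklist, record: PatientRecord,
                   annotations: Mapping[str, Sequence[ConceptAnnotation]]
                   ) -> ScreeningResult:
    """Evaluate every checklist item; order is preserved.

    ``relevant_docs`` is the set of documents cited as evidence by any
    verdict — the documents a reviewer should open first.
    """
    verdicts = tuple(
        eval_expr(item.expr, record, annotations, item.label, item.role)
        for item in checklist.items
    )
    relevant = frozenset(
        ev.doc_id
        for v in verdicts
        for ev in v.evidence
        if isinstance(ev, AnnotationEvidence)
    )
    return ScreeningResult(
        patient_id=record.patient_id,
        trial_name=checklist.trial_name,
        checklist_version=checklist.version,
        verdicts=verdicts,
        relevant_docs=relevant,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _evidence_to_obj(ev: Evidence) -> dict:
    if isinstance(ev, LabEvidence):
        return {"kind": "lab", "item_code": ev.item_code, "value": ev.value,
                "unit": ev.unit, "control_value": ev.control_value,
                "timestamp": ev.timestamp}
    return {"kind": "annotation", "doc_id": ev.doc_id, "start": ev.start,
            "end": ev.end, "cui": ev.cui, "matched_text": ev.matched_text}


def result_to_obj(result: ScreeningResult) -> dict:
    return {
        "patient_id": result.patient_id,
        "trial_name": result.trial_name,
        "checklist_version": result.checklist_version,
        "verdicts": [
            {
                "criterion_label": v.criterion_label,
                "role": v.role.value,
                "status": v.status.value,
                "evidence": [_evidence_to_obj(ev) for ev in v.evidence],
                "explanation": v.explanation,
            }
            for v in result.verdicts
        ],
        "relevant_docs": sorted(result.relevant_docs),
    }


def result_to_json(result: ScreeningResult) -> str:
    return json.dumps(result_to_obj(result), indent=2, ensure_ascii=False) + "\n"
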