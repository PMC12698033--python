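"""Machine-readable eligibility-rule expressions.

A trial checklist is an ordered list of inclusion/exclusion items, each
holding a rule-expression tree whose leaves are either numeric laboratory
criteria (``Platelets < 100,000``; ``APTT <= 1.4 x control``) or clinical
concept criteria (a concept family searched in selected EMR document
types), optionally restricted by a temporal window measured from the
patient's index time.  AND/OR/NOT combinators build compound criteria such
as "diabetes with prior stroke".

The types here are plain frozen dataclasses; they do not validate on
construction.  :func:`validate_expr` and :func:`validate_checklist` report
every invariant violation as data, so malformed trees can be inspected and
pointed at rather than merely raising.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Union

SCHEMA_VERSION = "1"


class Comparator(str, enum.Enum):
    LT = "LT"
    LE = "LE"
    GT = "GT"
    GE = "GE"
    EQ = "EQ"

    def apply(self, value: float, threshold: float) -> bool:
        if self is Comparator.LT:
            return value < threshold
        if self is Comparator.LE:
            return value <= threshold
        if self is Comparator.GT:
            return value > threshold
        if self is Comparator.GE:
            return value >= threshold
        return value == threshold

    @property
    def symbol(self) -> str:
        return {"LT": "<", "LE": "<=", "GT": ">", "GE": ">=", "EQ": "=="}[self.value]


COMPARATOR_SYMBOLS = {
    "<": Comparator.LT,
    "<=": Comparator.LE,
    ">": Comparator.GT,
    ">=": Comparator.GE,
    "=": Comparator.EQ,
    "==": Comparator.EQ,
}


class LabMode(str, enum.Enum):
    ABSOLUTE = "ABSOLUTE"
    RATIO_TO_CONTROL = "RATIO_TO_CONTROL"


class TimeUnit(str, enum.Enum):
    DAYS = "DAYS"
    MONTHS = "MONTHS"
    YEARS = "YEARS"


class Direction(str, enum.Enum):
    BEFORE_INDEX = "BEFORE_INDEX"
    AFTER_INDEX = "AFTER_INDEX"


class Role(str, enum.Enum):
    INCLUSION = "INCLUSION"
    EXCLUSION = "EXCLUSION"


@dataclass(frozen=True)
class TemporalWindow:
    """A calendar window anchored at the index time.

    The resolved interval is half-open: for BEFORE_INDEX it is
    ``[index - amount, index)`` so an event exactly ``amount`` before the
    index is inside and an event at the index itself is outside; for
    AFTER_INDEX it is ``[index, index + amount)``.  Month and year amounts
    use calendar arithmetic with month-end clamping, not fixed-length
    spans.
    """

    amount: int
    unit: TimeUnit
    direction: Direction = Direction.BEFORE_INDEX


@dataclass(frozen=True)
class LabItem:
    code: str
    name: str = ""

    @property
    def display(self) -> str:
        return self.name or self.code


@dataclass(frozen=True)
class LabCriterion:
    criterion_id: str
    item: LabItem
    comparator: Comparator
    threshold: float
    unit: str = ""
    mode: LabMode = LabMode.ABSOLUTE
    window: Optional[TemporalWindow] = None


@dataclass(frozen=True)
class ConceptRef:
    cui: str
    preferred_name: str


@dataclass(frozen=True)
class ConceptCriterion:
    criterion_id: str
    concepts: tuple[ConceptRef, ...]
    doc_types: frozenset[str]
    window: Optional[TemporalWindow] = None


Payload = Union[LabCriterion, ConceptCriterion]


class NodeKind(str, enum.Enum):
    LAB = "LAB"
    CONCEPT = "CONCEPT"
    AND = "AND"
    OR = "OR"
    NOT = "NOT"


@dataclass(frozen=True)
class RuleExpr:
    kind: NodeKind
    payload: Optional[Payload] = None
    children: tuple["RuleExpr", ...] = ()

    # -- constructors -------------------------------------------------
    @staticmethod
    def lab(crit: LabCriterion) -> "RuleExpr":
        return RuleExpr(NodeKind.LAB, payload=crit)

    @staticmethod
    def concept(crit: ConceptCriterion) -> "RuleExpr":
        return RuleExpr(NodeKind.CONCEPT, payload=crit)

    @staticmethod
    def and_(*children: "RuleExpr") -> "RuleExpr":
        return RuleExpr(NodeKind.AND, children=tuple(children))

    @staticmethod
    def or_(*children: "RuleExpr") -> "RuleExpr":
        return RuleExpr(NodeKind.OR, children=tuple(children))

    @staticmethod
    def not_(child: "RuleExpr") -> "RuleExpr":
        return RuleExpr(NodeKind.NOT, children=(child,))

    @property
    def is_leaf(self) -> bool:
        return self.kind in (NodeKind.LAB, NodeKind.CONCEPT)

    def walk(self, path: str = "$") -> Iterator[tuple[str, "RuleExpr"]]:
        """Yield (node-path, node) pairs in pre-order."""
        yield path, self
        for i, child in enumerate(self.children):
            yield from child.walk(f"{path}.{i}")


@dataclass(frozen=True)
class ChecklistItem:
    label: str
    role: Role
    expr: RuleExpr


@dataclass(frozen=True)
class Checklist:
    trial_name: str
    version: str
    items: tuple[ChecklistItem, ...]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: {self.message}"


def _validate_window(window: Optional[TemporalWindow], path: str,
                     out: list[Violation]) -> None:
    if window is None:
        return
    if not isinstance(window.amount, int) or isinstance(window.amount, bool) \
            or window.amount < 1:
        out.append(Violation(path, "window amount must be an integer >= 1"))
    if not isinstance(window.unit, TimeUnit):
        out.append(Violation(path, f"unknown window unit {window.unit!r}"))
    if not isinstance(window.direction, Direction):
        out.append(Violation(path, f"unknown window direction {window.direction!r}"))


def _validate_lab(crit: LabCriterion, path: str, out: list[Violation]) -> None:
    if not crit.criterion_id:
        out.append(Violation(path, "criterion_id must be non-empty"))
    if not isinstance(crit.comparator, Comparator):
        out.append(Violation(path, f"unknown comparator {crit.comparator!r}"))
    if not isinstance(crit.threshold, (int, float)) or isinstance(crit.threshold, bool) \
            or not math.isfinite(crit.threshold):
        out.append(Violation(path, "threshold must be a finite number"))
    elif crit.mode is LabMode.RATIO_TO_CONTROL and crit.threshold <= 0:
        out.append(Violation(path, "ratio-to-control threshold must be > 0"))
    if not isinstance(crit.mode, LabMode):
        out.append(Violation(path, f"unknown lab mode {crit.mode!r}"))
    if not crit.item.code:
        out.append(Violation(path, "lab item code must be non-empty"))
    _validate_window(crit.window, path, out)


def _validate_concept(crit: ConceptCriterion, path: str, out: list[Violation]) -> None:
    if not crit.criterion_id:
        out.append(Violation(path, "criterion_id must be non-empty"))
    if len(crit.concepts) < 1:
        out.append(Violation(path, "concept criterion requires >= 1 concept"))
    cuis = [c.cui for c in crit.concepts]
    if len(set(cuis)) != len(cuis):
        out.append(Violation(path, "concept CUIs must be unique within a criterion"))
    for c in crit.concepts:
        if not c.cui:
            out.append(Violation(path, "concept CUI must be non-empty"))
    if not crit.doc_types:
        out.append(Violation(path, "doc_types must be non-empty"))
    elif any(not t for t in crit.doc_types):
        out.append(Violation(path, "doc_types must not contain empty labels"))
    _validate_window(crit.window, path, out)


def validate_expr(expr: RuleExpr) -> list[Violation]:
    """Check every structural invariant of a rule tree.

    Returns an empty list iff the tree is well formed; each violation
    carries the pre-order path of the offending node (``$``, ``$.0``, ...).
    """
    out: list[Violation] = []
    for path, node in expr.walk():
        if node.kind in (NodeKind.LAB, NodeKind.CONCEPT):
            if node.children:
                out.append(Violation(path, "leaf node must have no children"))
            if node.kind is NodeKind.LAB:
                if isinstance(node.payload, LabCriterion):
                    _validate_lab(node.payload, path, out)
                else:
                    out.append(Violation(path, "LAB node requires a LabCriterion payload"))
            else:
                if isinstance(node.payload, ConceptCriterion):
                    _validate_concept(node.payload, path, out)
                else:
                    out.append(Violation(path, "CONCEPT node requires a ConceptCriterion payload"))
        elif node.kind in (NodeKind.AND, NodeKind.OR):
            if node.payload is not None:
                out.append(Violation(path, "combinator node must have no payload"))
            if len(node.children) < 2:
                out.append(Violation(path, f"{node.kind.value} requires >= 2 children"))
        elif node.kind is NodeKind.NOT:
            if node.payload is not None:
                out.append(Violation(path, "combinator node must have no payload"))
            if len(node.children) != 1:
                out.append(Violation(path, "NOT requires exactly 1 child"))
        else:
            out.append(Violation(path, f"unknown node kind {node.kind!r}"))
    return out


def validate_checklist(checklist: Checklist) -> list[Violation]:
    out: list[Violation] = []
    if not checklist.items:
        out.append(Violation("$", "checklist must contain >= 1 item"))
    labels = [it.label for it in checklist.items]
    if len(set(labels)) != len(labels):
        out.append(Violation("$", "item labels must be unique within a checklist"))
    for i, item in enumerate(checklist.items):
        if not isinstance(item.role, Role):
            out.append(Violation(f"$.items[{i}]", f"unknown role {item.role!r}"))
        out.extend(
            Violation(f"$.items[{i}].{v.path}", v.message)
            for v in validate_expr(item.expr)
        )
    return out


# ---------------------------------------------------------------------------
# Serialization (rule files)
# ---------------------------------------------------------------------------

class RuleFileError(ValueError):
    """Raised for malformed or unknown-version rule files."""


def _window_to_obj(w: Optional[TemporalWindow]):
    if w is None:
        return None
    return {"amount": w.amount, "unit": w.unit.value, "direction": w.direction.value}


def _expr_to_obj(expr: RuleExpr) -> dict:
    if expr.kind is NodeKind.LAB:
        c = expr.payload
        return {
            "kind": "LAB",
            "criterion_id": c.criterion_id,
            "item": {"code": c.item.code, "name": c.item.name},
            "comparator": c.comparator.value,
            "threshold": c.threshold,
            "unit": c.unit,
            "mode": c.mode.value,
            "window": _window_to_obj(c.window),
        }
    if expr.kind is NodeKind.CONCEPT:
        c = expr.payload
        return {
            "kind": "CONCEPT",
            "criterion_id": c.criterion_id,
            "concepts": [
                {"cui": r.cui, "preferred_name": r.preferred_name} for r in c.concepts
            ],
            "doc_types": sorted(c.doc_types),
            "window": _window_to_obj(c.window),
        }
    return {
        "kind": expr.kind.value,
        "children": [_expr_to_obj(ch) for ch in expr.children],
    }


_LAB_FIELDS = {"kind", "criterion_id", "item", "comparator", "threshold",
               "unit", "mode", "window"}
_CONCEPT_FIELDS = {"kind", "criterion_id", "concepts", "doc_types", "window"}
_COMBINATOR_FIELDS = {"kind", "children"}
_WINDOW_FIELDS = {"amount", "unit", "direction"}


def _reject_unknown(obj: dict, allowed: set[str], where: str) -> None:
    extra = set(obj) - allowed
    if extra:
        raise RuleFileError(f"unknown field(s) {sorted(extra)} in {where}")


def _enum_from(enum_cls, value, where: str):
    try:
        return enum_cls(value)
    except ValueError:
        raise RuleFileError(f"invalid {enum_cls.__name__} {value!r} in {where}") from None


def _window_from_obj(obj, where: str) -> Optional[TemporalWindow]:
    if obj is None:
        return None
    if not isinstance(obj, dict):
        raise RuleFileError(f"window must be an object in {where}")
    _reject_unknown(obj, _WINDOW_FIELDS, where)
    return TemporalWindow(
        amount=int(obj["amount"]),
        unit=_enum_from(TimeUnit, obj["unit"], where),
        direction=_enum_from(Direction, obj["direction"], where),
    )


def _expr_from_obj(obj, where: str) -> RuleExpr:
    if not isinstance(obj, dict) or "kind" not in obj:
        raise RuleFileError(f"expression node must be an object with 'kind' in {where}")
    kind = _enum_from(NodeKind, obj["kind"], where)
    if kind is NodeKind.LAB:
        _reject_unknown(obj, _LAB_FIELDS, where)
        item = obj["item"]
        _reject_unknown(item, {"code", "name"}, f"{where}.item")
        crit = LabCriterion(
            criterion_id=str(obj["criterion_id"]),
            item=LabItem(code=str(item["code"]), name=str(item.get("name", ""))),
            comparator=_enum_from(Comparator, obj["comparator"], where),
            threshold=float(obj["threshold"]),
            unit=str(obj.get("unit", "")),
            mode=_enum_from(LabMode, obj["mode"], where),
            window=_window_from_obj(obj.get("window"), where),
        )
        return RuleExpr.lab(crit)
    if kind is NodeKind.CONCEPT:
        _reject_unknown(obj, _CONCEPT_FIELDS, where)
        refs = []
        for i, r in enumerate(obj["concepts"]):
            _reject_unknown(r, {"cui", "preferred_name"}, f"{where}.concepts[{i}]")
            refs.append(ConceptRef(cui=str(r["cui"]),
                                   preferred_name=str(r["preferred_name"])))
        crit = ConceptCriterion(
            criterion_id=str(obj["criterion_id"]),
            concepts=tuple(refs),
            doc_types=frozenset(str(t) for t in obj["doc_types"]),
            window=_window_from_obj(obj.get("window"), where),
        )
        return RuleExpr.concept(crit)
    _reject_unknown(obj, _COMBINATOR_FIELDS, where)
    children = tuple(
        _expr_from_obj(ch, f"{where}.children[{i}]")
        for i, ch in enumerate(obj.get("children", []))
    )
    return RuleExpr(kind, children=children)


def checklist_to_obj(checklist: Checklist) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "trial_name": checklist.trial_name,
        "version": checklist.version,
        "items": [
            {
                "label": item.label,
                "role": item.role.value,
                "expr": _expr_to_obj(item.expr),
            }
            for item in checklist.items
        ],
    }


def checklist_from_obj(obj: dict) -> Checklist:
    if not isinstance(obj, dict):
        raise RuleFileError("rule file must be a JSON object")
    version = obj.get("schema_version")
    if version != SCHEMA_VERSION:
        raise RuleFileError(
            f"unknown schema version {version!r} (supported: {SCHEMA_VERSION})")
    _reject_unknown(obj, {"schema_version", "trial_name", "version", "items"}, "$")
    items = []
    for i, it in enumerate(obj.get("items", [])):
        _reject_unknown(it, {"label", "role", "expr"}, f"$.items[{i}]")
        items.append(ChecklistItem(
            label=str(it["label"]),
            role=_enum_from(Role, it["role"], f"$.items[{i}]"),
            expr=_expr_from_obj(it["expr"], f"$.items[{i}].expr"),
        ))
    return Checklist(
        trial_name=str(obj.get("trial_name", "")),
        version=str(obj.get("version", "")),
        items=tuple(items),
    )


def serialize(checklist: Checklist) -> bytes:
    """Encode a checklist as a versioned rule file (UTF-8 JSON)."""
    obj = checklist_to_obj(checklist)
    return (json.dumps(obj, indent=2, ensure_ascii=False, sort_keys=False)
            + "\n").encode("utf-8")


def deserialize(data: bytes) -> Checklist:
    try:
        obj = json.loads(data.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise RuleFileError(f"malformed rule file: {exc}") from exc
    return checklist_from_obj(obj)


def load_checklist(path) -> Checklist:
    with open(path, "rb") as fh:
        return deserialize(fh.read())


def save_checklist(checklist: Checklist, path) -> None:
    with open(path, "wb") as fh:
        fh.write(serialize(checklist))
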