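"""Text DSL for authoring eligibility checklists.

One statement per checklist item, a header line naming the trial, and
``#`` comments.  Example::

    checklist "NINDS rt-PA style" version "1.0"

    exclude "Platelet count below 100,000": lab "PLT" < 100000
    include "APTT within limits":
        lab "APTT" <= 1.4 x control within 7 days before index
    exclude "Headache or head injury within 3 years":
        (concept "Headache" in [outpatient note, admission note]
            within 3 years before index)
        or (concept "Head injury" in [outpatient note, admission note]
            within 3 years before index)

Grammar (case-insensitive keywords)::

    file     := header item*
    header   := 'checklist' STRING 'version' STRING
    item     := ('include' | 'exclude') STRING ':' expr
    expr     := and_expr ('or' and_expr)*
    and_expr := unary ('and' unary)*
    unary    := 'not' unary | '(' expr ')' | lab | concept
    lab      := 'lab' STRING cmp NUMBER ('x' 'control')? ('unit' STRING)? window?
    concept  := 'concept' cref (',' cref)* 'in' '[' dtype (',' dtype)* ']' window?
    cref     := STRING ('cui' STRING)?
    window   := 'within' NUMBER ('days'|'months'|'years') ('before'|'after') 'index'

Criterion identifiers are assigned positionally (``i<item>.c<leaf>``) so a
pretty-printed checklist re-parses to a structurally identical tree.
Concept names resolve against a lexicon when one is supplied; otherwise
the name itself serves as the concept identifier unless an explicit
``cui`` clause is given.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .rules import (
    COMPARATOR_SYMBOLS,
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
    TemporalWindow,
    TimeUnit,
)


class DslError(ValueError):
    """A DSL syntax or resolution error with source position."""

    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>[ \t\r]+)
  | (?P<comment>\#[^\n]*)
  | (?P<newline>\n)
  | (?P<string>"(?:[^"\\\n]|\\.)*")
  | (?P<number>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)
  | (?P<word>[A-Za-z_][A-Za-z0-9_\-]*)
  | (?P<sym><=|>=|==|[<>=():,\[\]\-])
    """,
    re.VERBOSE,
)

_KEYWORDS = {
    "checklist", "version", "include", "exclude", "lab", "concept", "cui",
    "in", "within", "before", "after", "index", "and", "or", "not", "x",
    "control", "unit", "day", "days", "month", "months", "year", "years",
}


@dataclass(frozen=True)
class _Token:
    kind: str  # STRING | NUMBER | WORD | SYM | EOF
    value: str
    line: int
    column: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    line, line_start = 1, 0
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise DslError(f"unexpected character {text[pos]!r}",
                           line, pos - line_start + 1)
        col = pos - line_start + 1
        pos = m.end()
        if m.lastgroup == "newline":
            line += 1
            line_start = pos
            continue
        if m.lastgroup in ("ws", "comment"):
            continue
        kind = {"string": "STRING", "number": "NUMBER",
                "word": "WORD", "sym": "SYM"}[m.lastgroup]
        tokens.append(_Token(kind, m.group(), line, col))
    tokens.append(_Token("EOF", "", line, len(text) - line_start + 1))
    return tokens


def _unquote(raw: str) -> str:
    body = raw[1:-1]
    out = []
    i = 0
    while i < len(body):
        if body[i] == "\\" and i + 1 < len(body):
            out.append(body[i + 1])
            i += 2
        else:
            out.append(body[i])
            i += 1
    return "".join(out)


def _quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

_UNIT_WORDS = {
    "day": TimeUnit.DAYS, "days": TimeUnit.DAYS,
    "month": TimeUnit.MONTHS, "months": TimeUnit.MONTHS,
    "year": TimeUnit.YEARS, "years": TimeUnit.YEARS,
}


class _Parser:
    def __init__(self, tokens: list[_Token], lexicon=None,
                 known_lab_items: Optional[Sequence[str]] = None):
        self.tokens = tokens
        self.pos = 0
        self.lexicon = lexicon
        self.known_lab_items = (
            {c.lower() for c in known_lab_items} if known_lab_items is not None
            else None
        )
        self._item_no = 0
        self._leaf_no = 0

    # -- token helpers ------------------------------------------------
    def peek(self) -> _Token:
        return self.tokens[self.pos]

    def next(self) -> _Token:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def error(self, message: str, tok: Optional[_Token] = None):
        tok = tok or self.peek()
        raise DslError(message, tok.line, tok.column)

    def at_keyword(self, *words: str) -> bool:
        tok = self.peek()
        return tok.kind == "WORD" and tok.value.lower() in words

    def expect_keyword(self, *words: str) -> _Token:
        if not self.at_keyword(*words):
            self.error(f"expected {' or '.join(repr(w) for w in words)}, "
                       f"got {self.peek().value!r}")
        return self.next()

    def expect(self, kind: str, what: str) -> _Token:
        if self.peek().kind != kind:
            self.error(f"expected {what}, got {self.peek().value!r}")
        return self.next()

    def expect_sym(self, sym: str) -> _Token:
        tok = self.peek()
        if tok.kind != "SYM" or tok.value != sym:
            self.error(f"expected {sym!r}, got {tok.value!r}")
        return self.next()

    def string(self, what: str) -> str:
        return _unquote(self.expect("STRING", what).value)

    # -- grammar ------------------------------------------------------
    def parse_file(self) -> Checklist:
        self.expect_keyword("checklist")
        trial_name = self.string("trial name string")
        self.expect_keyword("version")
        version = self.string("version string")
        items = []
        while not self.peek().kind == "EOF":
            items.append(self.parse_item())
        if not items:
            self.error("checklist has no items")
        return Checklist(trial_name=trial_name, version=version,
                         items=tuple(items))

    def parse_item(self) -> ChecklistItem:
        tok = self.expect_keyword("include", "exclude")
        role = Role.INCLUSION if tok.value.lower() == "include" else Role.EXCLUSION
        self._item_no += 1
        self._leaf_no = 0
        label = self.string("criterion label string")
        self.expect_sym(":")
        expr = self.parse_expr()
        return ChecklistItem(label=label, role=role, expr=expr)

    def parse_expr(self) -> RuleExpr:
        node = self.parse_and()
        children = [node]
        while self.at_keyword("or"):
            self.next()
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else RuleExpr.or_(*children)

    def parse_and(self) -> RuleExpr:
        children = [self.parse_unary()]
        while self.at_keyword("and"):
            self.next()
            children.append(self.parse_unary())
        return children[0] if len(children) == 1 else RuleExpr.and_(*children)

    def parse_unary(self) -> RuleExpr:
        if self.at_keyword("not"):
            self.next()
            return RuleExpr.not_(self.parse_unary())
        tok = self.peek()
        if tok.kind == "SYM" and tok.value == "(":
            self.next()
            expr = self.parse_expr()
            self.expect_sym(")")
            return expr
        if self.at_keyword("lab"):
            return self.parse_lab()
        if self.at_keyword("concept"):
            return self.parse_concept()
        self.error(f"expected a criterion, '(' or 'not', got {tok.value!r}")

    def _next_criterion_id(self) -> str:
        self._leaf_no += 1
        return f"i{self._item_no}.c{self._leaf_no}"

    def parse_lab(self) -> RuleExpr:
        self.next()  # 'lab'
        name_tok = self.peek()
        name = self.string("lab item string")
        if self.known_lab_items is not None and name.lower() not in self.known_lab_items:
            self.error(f"undeclared lab item {name!r}", name_tok)
        sym_tok = self.expect("SYM", "a comparator")
        comparator = COMPARATOR_SYMBOLS.get(sym_tok.value)
        if comparator is None:
            self.error(f"expected a comparator, got {sym_tok.value!r}", sym_tok)
        sign = 1.0
        if self.peek().kind == "SYM" and self.peek().value == "-":
            self.next()
            sign = -1.0
        threshold = sign * float(self.expect("NUMBER", "a threshold").value)
        mode = LabMode.ABSOLUTE
        if self.at_keyword("x"):
            self.next()
            self.expect_keyword("control")
            mode = LabMode.RATIO_TO_CONTROL
        unit = ""
        if self.at_keyword("unit"):
            self.next()
            unit = self.string("unit string")
        window = self.parse_window_opt()
        crit = LabCriterion(
            criterion_id=self._next_criterion_id(),
            item=LabItem(code=name),
            comparator=comparator,
            threshold=threshold,
            unit=unit,
            mode=mode,
            window=window,
        )
        return RuleExpr.lab(crit)

    def parse_concept(self) -> RuleExpr:
        self.next()  # 'concept'
        refs = [self.parse_concept_ref()]
        while self.peek().kind == "SYM" and self.peek().value == ",":
            self.next()
            refs.append(self.parse_concept_ref())
        self.expect_keyword("in")
        self.expect_sym("[")
        doc_types = [self.parse_doc_type()]
        while self.peek().kind == "SYM" and self.peek().value == ",":
            self.next()
            doc_types.append(self.parse_doc_type())
        self.expect_sym("]")
        window = self.parse_window_opt()
        crit = ConceptCriterion(
            criterion_id=self._next_criterion_id(),
            concepts=tuple(refs),
            doc_types=frozenset(doc_types),
            window=window,
        )
        return RuleExpr.concept(crit)

    def parse_concept_ref(self) -> ConceptRef:
        name_tok = self.peek()
        name = self.string("concept name string")
        cui = None
        if self.at_keyword("cui"):
            self.next()
            cui = self.string("CUI string")
        if cui is None:
            if self.lexicon is not None:
                entry = self.lexicon.find(name)
                if entry is None:
                    self.error(f"concept {name!r} not found in lexicon", name_tok)
                return ConceptRef(cui=entry.cui, preferred_name=entry.preferred_name)
            cui = name
        return ConceptRef(cui=cui, preferred_name=name)

    def parse_doc_type(self) -> str:
        # either a quoted string or a run of bare words ("outpatient note")
        if self.peek().kind == "STRING":
            return self.string("document type")
        words = []
        while self.peek().kind in ("WORD", "NUMBER"):
            words.append(self.next().value)
        if not words:
            self.error("expected a document type")
        return " ".join(words)

    def parse_window_opt(self) -> Optional[TemporalWindow]:
        if not self.at_keyword("within"):
            return None
        self.next()
        amount_tok = self.expect("NUMBER", "a window amount")
        if not amount_tok.value.isdigit():
            self.error("window amount must be an integer", amount_tok)
        amount = int(amount_tok.value)
        unit_tok = self.expect("WORD", "a time unit")
        unit = _UNIT_WORDS.get(unit_tok.value.lower())
        if unit is None:
            self.error(f"unknown time unit {unit_tok.value!r}", unit_tok)
        dir_tok = self.expect_keyword("before", "after")
        direction = (Direction.BEFORE_INDEX if dir_tok.value.lower() == "before"
                     else Direction.AFTER_INDEX)
        self.expect_keyword("index")
        return TemporalWindow(amount=amount, unit=unit, direction=direction)


def parse_dsl(text: str, lexicon=None,
              known_lab_items: Optional[Sequence[str]] = None) -> Checklist:
    """Parse DSL source into a :class:`Checklist`.

    Parameters
    ----------
    text:
        DSL source.
    lexicon:
        Optional :class:`~trialscreen.tagger.Lexicon`; when given, concept
        names without an explicit ``cui`` clause must resolve to an entry
        (by preferred name or surface form) or a resolution error is
        raised.
    known_lab_items:
        Optional collection of declared lab item codes; when given, a lab
        criterion naming an unknown item is a resolution error.
    """
    return _Parser(_tokenize(text), lexicon, known_lab_items).parse_file()


# ---------------------------------------------------------------------------
# Pretty printer (canonical form; parse_dsl(pretty_print(c)) == c)
# ---------------------------------------------------------------------------

def _format_number(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def _format_window(w: Optional[TemporalWindow]) -> str:
    if w is None:
        return ""
    unit = w.unit.value.lower()
    direction = "before" if w.direction is Direction.BEFORE_INDEX else "after"
    return f" within {w.amount} {unit} {direction} index"


_BARE_DOC_TYPE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_\-]*(?: [A-Za-z0-9_\-]+)*$")


def _format_doc_type(t: str) -> str:
    words = t.split(" ")
    if _BARE_DOC_TYPE_RE.match(t) and not any(
            w.lower() in _KEYWORDS for w in words):
        return t
    return _quote(t)


def _format_leaf(expr: RuleExpr) -> str:
    if expr.kind is NodeKind.LAB:
        c = expr.payload
        parts = [f"lab {_quote(c.item.code)} {c.comparator.symbol} "
                 f"{_format_number(c.threshold)}"]
        if c.mode is LabMode.RATIO_TO_CONTROL:
            parts.append(" x control")
        if c.unit:
            parts.append(f" unit {_quote(c.unit)}")
        parts.append(_format_window(c.window))
        return "".join(parts)
    c = expr.payload
    refs = ", ".join(
        _quote(r.preferred_name) if r.cui == r.preferred_name
        else f"{_quote(r.preferred_name)} cui {_quote(r.cui)}"
        for r in c.concepts
    )
    types = ", ".join(_format_doc_type(t) for t in sorted(c.doc_types))
    return f"concept {refs} in [{types}]{_format_window(c.window)}"


def _format_expr(expr: RuleExpr) -> str:
    if expr.is_leaf:
        return _format_leaf(expr)
    if expr.kind is NodeKind.NOT:
        child = expr.children[0]
        inner = _format_expr(child)
        if not child.is_leaf and child.kind is not NodeKind.NOT:
            inner = f"({inner})"
        return f"not {inner}"
    joiner = " and " if expr.kind is NodeKind.AND else " or "
    parts = []
    for child in expr.children:
        inner = _format_expr(child)
        if child.kind in (NodeKind.AND, NodeKind.OR):
            inner = f"({inner})"
        parts.append(inner)
    return joiner.join(parts)


def pretty_print(checklist: Checklist) -> str:
    """Render a checklist as canonical DSL source."""
    lines = [f"checklist {_quote(checklist.trial_name)} "
             f"version {_quote(checklist.version)}", ""]
    for item in checklist.items:
        keyword = "include" if item.role is Role.INCLUSION else "exclude"
        lines.append(f"{keyword} {_quote(item.label)}: {_format_expr(item.expr)}")
    return "\n".join(lines) + "\n"
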