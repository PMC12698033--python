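"""Lexicon-based clinical concept extraction with negation detection.

A deterministic dictionary tagger: each lexicon entry maps a concept
unique identifier (CUI) and its semantic types to a set of surface forms
(synonyms, acronyms, abbreviations, and — for broad classes such as
"Anticoagulant" — enumerated member drug names).  Matching is greedy
longest-match, left-to-right, non-overlapping, token-boundary-aware, and
case-insensitive unless a form is flagged case-sensitive (useful for
short acronyms like ``MI``).

Negation is trigger/scope based: a mention is negated when a pre-trigger
phrase ("no history of", "denies") ends within ``scope_window`` tokens
before it, or a post-trigger ("was ruled out") starts within
``scope_window`` tokens after it, with no scope-terminating token ("but",
"however") in between.

Any alternative extractor (for example a wrapper around an external
concept-mapping engine) can replace this one downstream as long as it
provides the :func:`annotate_record` signature: a mapping from doc_id to
annotation lists.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, replace
from datetime import datetime
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .emr import ClinicalDocument, PatientRecord, parse_timestamp

logger = logging.getLogger(__name__)

# Unicode word tokens; hyphenated terms stay single tokens.
_TOKEN_RE = re.compile(r"\w+(?:-\w+)*", re.UNICODE)


def tokenize(text: str) -> list[tuple[int, int, str]]:
    """Return (start, end, token) triples over ``text``."""
    return [(m.start(), m.end(), m.group()) for m in _TOKEN_RE.finditer(text)]


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfaceForm:
    text: str
    case_sensitive: bool = False


@dataclass(frozen=True)
class LexiconEntry:
    cui: str
    preferred_name: str
    semantic_types: tuple[str, ...]
    surface_forms: tuple[SurfaceForm, ...]

    @property
    def primary_semantic_type(self) -> str:
        return self.semantic_types[0]


class LexiconError(ValueError):
    pass


@dataclass(frozen=True)
class Lexicon:
    entries: tuple[LexiconEntry, ...]

    def __post_init__(self):
        seen: set[str] = set()
        for entry in self.entries:
            if not entry.cui:
                raise LexiconError("lexicon entry with empty CUI")
            if entry.cui in seen:
                raise LexiconError(f"duplicate CUI {entry.cui!r}")
            seen.add(entry.cui)
            if not entry.surface_forms:
                raise LexiconError(f"{entry.cui}: entry has no surface forms")
            if not entry.semantic_types:
                raise LexiconError(f"{entry.cui}: entry has no semantic types")
            for form in entry.surface_forms:
                if not form.text.strip():
                    raise LexiconError(f"{entry.cui}: empty surface form")

    def entry(self, cui: str) -> Optional[LexiconEntry]:
        for e in self.entries:
            if e.cui == cui:
                return e
        return None

    def find(self, name: str) -> Optional[LexiconEntry]:
        """Resolve a preferred name or surface form (case-insensitive)."""
        needle = name.casefold()
        for e in self.entries:
            if e.preferred_name.casefold() == needle:
                return e
        for e in self.entries:
            for form in e.surface_forms:
                if form.text.casefold() == needle:
                    return e
        return None


def read_lexicon_csv(path) -> Lexicon:
    """Load a lexicon from a CSV with one row per (CUI, surface form).

    Columns: cui, preferred_name, semantic_types (``|``-separated),
    surface_form, case_sensitive (0/1).  Rows sharing a CUI accumulate
    surface forms; entry order follows first appearance.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"cui", "preferred_name", "semantic_types", "surface_form",
                "case_sensitive"}
    missing = required - set(frame.columns)
    if missing:
        raise LexiconError(f"{path}: lexicon missing column(s) {sorted(missing)}")
    order: list[str] = []
    meta: dict[str, tuple[str, tuple[str, ...]]] = {}
    forms: dict[str, list[SurfaceForm]] = {}
    for row in frame.itertuples(index=False):
        cui = row.cui
        if cui not in meta:
            order.append(cui)
            meta[cui] = (row.preferred_name,
                         tuple(t for t in row.semantic_types.split("|") if t))
            forms[cui] = []
        forms[cui].append(SurfaceForm(
            text=row.surface_form,
            case_sensitive=row.case_sensitive.strip() in ("1", "true", "True"),
        ))
    return Lexicon(tuple(
        LexiconEntry(cui=cui, preferred_name=meta[cui][0],
                     semantic_types=meta[cui][1],
                     surface_forms=tuple(forms[cui]))
        for cui in order
    ))


def write_lexicon_csv(lexicon: Lexicon, path) -> None:
    rows = [
        {
            "cui": e.cui,
            "preferred_name": e.preferred_name,
            "semantic_types": "|".join(e.semantic_types),
            "surface_form": f.text,
            "case_sensitive": int(f.case_sensitive),
        }
        for e in lexicon.entries
        for f in e.surface_forms
    ]
    pd.DataFrame(rows, columns=["cui", "preferred_name", "semantic_types",
                                "surface_form", "case_sensitive"]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConceptAnnotation:
    doc_id: str
    start: int
    end: int
    matched_text: str
    cui: str
    preferred_name: str
    semantic_type: str
    negated: bool
    doc_timestamp: datetime

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def write_annotations_jsonl(annotations: Iterable[ConceptAnnotation], path,
                            source: Optional[str] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ann in annotations:
            obj = {
                "doc_id": ann.doc_id,
                "start": ann.start,
                "end": ann.end,
                "matched_text": ann.matched_text,
                "cui": ann.cui,
                "preferred_name": ann.preferred_name,
                "semantic_type": ann.semantic_type,
                "negated": ann.negated,
                "doc_timestamp": ann.doc_timestamp.isoformat(),
            }
            if source is not None:
                obj["source"] = source
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_annotations_jsonl(path) -> list[ConceptAnnotation]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(ConceptAnnotation(
                doc_id=obj["doc_id"],
                start=int(obj["start"]),
                end=int(obj["end"]),
                matched_text=obj["matched_text"],
                cui=obj["cui"],
                preferred_name=obj["preferred_name"],
                semantic_type=obj["semantic_type"],
                negated=bool(obj["negated"]),
                doc_timestamp=parse_timestamp(obj["doc_timestamp"]),
            ))
    return out


# ---------------------------------------------------------------------------
# Tagging
# ---------------------------------------------------------------------------

def _form_tokens(form: SurfaceForm) -> tuple[str, ...]:
    tokens = tuple(t for _, _, t in tokenize(form.text))
    return tokens if form.case_sensitive else tuple(t.casefold() for t in tokens)


class _MatchIndex:
    """Token-sequence index over a lexicon; first-declared entry wins."""

    def __init__(self, lexicon: Lexicon):
        self.exact: dict[tuple[str, ...], LexiconEntry] = {}
        self.folded: dict[tuple[str, ...], LexiconEntry] = {}
        self.max_len = 0
        for entry in lexicon.entries:
            for form in entry.surface_forms:
                key = _form_tokens(form)
                if not key:
                    continue
                table = self.exact if form.case_sensitive else self.folded
                prior = table.get(key)
                if prior is not None:
                    if prior.cui != entry.cui:
                        logger.warning(
                            "ambiguous surface form %r: kept %s, ignored %s",
                            form.text, prior.cui, entry.cui)
                    continue
                table[key] = entry
                self.max_len = max(self.max_len, len(key))

    def lookup(self, tokens: Sequence[str], i: int) -> tuple[int, Optional[LexiconEntry]]:
        """Longest match starting at token ``i``; returns (length, entry)."""
        limit = min(self.max_len, len(tokens) - i)
        for n in range(limit, 0, -1):
            window = tuple(tokens[i:i + n])
            entry = self.exact.get(window)
            if entry is None:
                entry = self.folded.get(tuple(t.casefold() for t in window))
            if entry is not None:
                return n, entry
        return 0, None


def tag_document(doc: ClinicalDocument, lexicon: Lexicon) -> list[ConceptAnnotation]:
    """Extract concept mentions from one document.

    Greedy longest-match over token sequences; emitted annotations are
    non-overlapping and carry the entry's CUI and primary semantic type.
    Negation flags are all ``False``; see :func:`detect_negation`.
    """
    index = _MatchIndex(lexicon)
    toks = tokenize(doc.text)
    texts = [t for _, _, t in toks]
    out: list[ConceptAnnotation] = []
    i = 0
    while i < len(toks):
        n, entry = index.lookup(texts, i)
        if entry is None:
            i += 1
            continue
        start = toks[i][0]
        end = toks[i + n - 1][1]
        out.append(ConceptAnnotation(
            doc_id=doc.doc_id,
            start=start,
            end=end,
            matched_text=doc.text[start:end],
            cui=entry.cui,
            preferred_name=entry.preferred_name,
            semantic_type=entry.primary_semantic_type,
            negated=False,
            doc_timestamp=doc.timestamp,
        ))
        i += n
    return out


def filter_semantic_types(annotations: Sequence[ConceptAnnotation],
                          allowed: Iterable[str]) -> list[ConceptAnnotation]:
    """Keep annotations whose semantic type is in ``allowed`` (order kept)."""
    allowed = set(allowed)
    return [a for a in annotations if a.semantic_type in allowed]


# ---------------------------------------------------------------------------
# Negation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NegationRuleSet:
    pre_triggers: tuple[str, ...]
    post_triggers: tuple[str, ...]
    terminators: tuple[str, ...]
    scope_window: int = 6

    def __post_init__(self):
        if not self.pre_triggers or not self.post_triggers:
            raise ValueError("trigger lists must be non-empty")
        if self.scope_window < 1:
            raise ValueError("scope_window must be >= 1")


def read_negation_rules(path) -> NegationRuleSet:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    return NegationRuleSet(
        pre_triggers=tuple(obj["pre_triggers"]),
        post_triggers=tuple(obj["post_triggers"]),
        terminators=tuple(obj.get("terminators", [])),
        scope_window=int(obj.get("scope_window", 6)),
    )


def default_negation_rules() -> NegationRuleSet:
    """The negation rule set shipped with the package."""
    ref = resources.files("trialscreen").joinpath("data/negation_rules.json")
    with resources.as_file(ref) as path:
        return read_negation_rules(path)


def _trigger_occurrences(texts: Sequence[str], triggers: Iterable[str]
                         ) -> list[tuple[int, int]]:
    """Token index ranges [start, end) of every trigger occurrence."""
    occ: list[tuple[int, int]] = []
    folded = [t.casefold() for t in texts]
    for trigger in triggers:
        key = [t.casefold() for _, _, t in tokenize(trigger)]
        if not key:
            continue
        n = len(key)
        for i in range(len(folded) - n + 1):
            if folded[i:i + n] == key:
                occ.append((i, i + n))
    return occ


def detect_negation(doc_text: str, annotations: Sequence[ConceptAnnotation],
                    rules: NegationRuleSet) -> list[ConceptAnnotation]:
    """Set negation flags on annotations of ``doc_text``.

    A mention is negated iff a pre-trigger ends at most ``scope_window``
    tokens before its first token (or a post-trigger starts at most
    ``scope_window`` tokens after its last token) with no terminator
    token in the gap.
    """
    toks = tokenize(doc_text)
    texts = [t for _, _, t in toks]
    folded = [t.casefold() for t in texts]
    terminator_set = {t.casefold() for t in rules.terminators}
    term_positions = [i for i, t in enumerate(folded) if t in terminator_set]
    pre = _trigger_occurrences(texts, rules.pre_triggers)
    post = _trigger_occurrences(texts, rules.post_triggers)

    # map character offsets to token indices
    start_to_idx = {s: i for i, (s, _, _) in enumerate(toks)}
    end_to_idx = {e: i for i, (_, e, _) in enumerate(toks)}

    def has_terminator(lo: int, hi: int) -> bool:
        return any(lo <= p < hi for p in term_positions)

    out: list[ConceptAnnotation] = []
    for ann in annotations:
        a = start_to_idx.get(ann.start)
        b_idx = end_to_idx.get(ann.end)
        if a is None or b_idx is None:
            raise ValueError(
                f"annotation span {ann.span} does not align with token "
                f"boundaries of the document")
        b = b_idx + 1  # exclusive token end
        negated = False
        for (ts, te) in pre:
            if te <= a and a - te < rules.scope_window and not has_terminator(te, a):
                negated = True
                break
        if not negated:
            for (ts, te) in post:
                if ts >= b and ts - b < rules.scope_window \
                        and not has_terminator(b, ts):
                    negated = True
                    break
        out.append(replace(ann, negated=negated))
    return out


# ---------------------------------------------------------------------------
# Record-level pipeline
# ---------------------------------------------------------------------------

def annotate_record(record: PatientRecord, lexicon: Lexicon,
                    allowed_types: Optional[Iterable[str]] = None,
                    rules: Optional[NegationRuleSet] = None
                    ) -> dict[str, list[ConceptAnnotation]]:
    """Tag, filter, and negation-flag every document of a record.

    Returns a mapping doc_id -> annotations (every document gets a key,
    possibly with an empty list).  ``allowed_types=None`` disables the
    semantic-type filter.
    """
    if rules is None:
        rules = default_negation_rules()
    out: dict[str, list[ConceptAnnotation]] = {}
    for doc in record.documents:
        anns = tag_document(doc, lexicon)
        if allowed_types is not None:
            anns = filter_semantic_types(anns, allowed_types)
        anns = detect_negation(doc.text, anns, rules)
        out[doc.doc_id] = anns
    return out
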