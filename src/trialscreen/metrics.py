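"""Extraction scoring and study outcome scores.

``concept_prf`` scores automated concept extraction against expert
gold-standard span annotations, per CUI.  A predicted *affirmed*
annotation matches a gold affirmed item iff the CUIs agree and the spans
overlap (default policy; exact-span matching is available).  Negated
predictions never count as detections, and negated gold items are not
detection targets — they are audit records of correctly absent findings.
Matching is one-to-one (maximum bipartite matching), so one prediction
cannot absorb two gold mentions.

Zero-denominator precision/recall are reported as ``None`` ("n/a"), not
coerced to 0 or 1.

Also here: the checklist accuracy score (mean per-criterion correctness,
maximum 1), the NASA-TLX weighted workload score (six 0-20 subscales,
pairwise-comparison weights summing to 15, total on 0-100), and the
standard SUS usability score (ten 1-5 Likert items mapped to 0-100).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Optional, Sequence

import pandas as pd

from .tagger import ConceptAnnotation


class MetricsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Gold annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoldItem:
    doc_id: str
    start: int
    end: int
    cui: str
    negated: bool = False


@dataclass(frozen=True)
class GoldAnnotationSet:
    items: tuple[GoldItem, ...]

    def by_doc(self) -> dict[str, list[GoldItem]]:
        out: dict[str, list[GoldItem]] = {}
        for item in self.items:
            out.setdefault(item.doc_id, []).append(item)
        return out


def read_gold_jsonl(path) -> GoldAnnotationSet:
    import json

    items = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            items.append(GoldItem(
                doc_id=obj["doc_id"], start=int(obj["start"]),
                end=int(obj["end"]), cui=obj["cui"],
                negated=bool(obj.get("negated", False)),
            ))
    return GoldAnnotationSet(tuple(items))


def write_gold_jsonl(gold: GoldAnnotationSet, path) -> None:
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for item in gold.items:
            fh.write(json.dumps({
                "doc_id": item.doc_id, "start": item.start, "end": item.end,
                "cui": item.cui, "negated": item.negated, "source": "gold",
            }) + "\n")


# ---------------------------------------------------------------------------
# Precision / recall / F1
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PRFRow:
    cui: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> Optional[float]:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None

    @property
    def recall(self) -> Optional[float]:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)


@dataclass(frozen=True)
class PRFReport:
    rows: tuple[PRFRow, ...]

    def row(self, cui: str) -> Optional[PRFRow]:
        for r in self.rows:
            if r.cui == cui:
                return r
        return None

    @property
    def micro(self) -> PRFRow:
        return PRFRow(
            cui="__micro__",
            tp=sum(r.tp for r in self.rows),
            fp=sum(r.fp for r in self.rows),
            fn=sum(r.fn for r in self.rows),
        )

    def to_frame(self) -> pd.DataFrame:
        def fmt(x: Optional[float]):
            return "n/a" if x is None else round(x, 4)

        return pd.DataFrame([
            {"cui": r.cui, "tp": r.tp, "fp": r.fp, "fn": r.fn,
             "precision": fmt(r.precision), "recall": fmt(r.recall),
             "f1": fmt(r.f1)}
            for r in self.rows
        ], columns=["cui", "tp", "fp", "fn", "precision", "recall", "f1"])


def _spans_match(pred: tuple[int, int], gold: tuple[int, int],
                 policy: str) -> bool:
    if policy == "exact":
        return pred == gold
    if policy == "overlap":
        return pred[0] < gold[1] and gold[0] < pred[1]
    raise MetricsError(f"unknown match policy {policy!r}")


def _max_matching(adj: list[list[int]], n_right: int) -> int:
    """Maximum bipartite matching size via augmenting paths."""
    match_right = [-1] * n_right

    def augment(u: int, seen: list[bool]) -> bool:
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                if match_right[v] == -1 or augment(match_right[v], seen):
                    match_right[v] = u
                    return True
        return False

    size = 0
    for u in range(len(adj)):
        if augment(u, [False] * n_right):
            size += 1
    return size


def concept_prf(predicted: Mapping[str, Sequence[ConceptAnnotation]],
                gold: GoldAnnotationSet,
                match_policy: str = "overlap") -> PRFReport:
    """Score predicted annotations against gold, per CUI.

    ``predicted`` maps doc_id to annotation lists (every scored document
    must appear as a key, possibly empty); a gold item naming a doc_id
    absent from ``predicted`` is an error.
    """
    known_docs = set(predicted)
    for item in gold.items:
        if item.doc_id not in known_docs:
            raise MetricsError(
                f"gold annotation references unknown doc_id {item.doc_id!r}")

    pred_affirmed: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for doc_id, anns in predicted.items():
        for ann in anns:
            if ann.negated:
                continue  # negated predictions are not detections
            pred_affirmed.setdefault((ann.cui, doc_id), []).append(ann.span)
    gold_affirmed: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for item in gold.items:
        if item.negated:
            continue
        gold_affirmed.setdefault((item.cui, item.doc_id), []).append(
            (item.start, item.end))

    cuis = sorted({cui for cui, _ in pred_affirmed}
                  | {cui for cui, _ in gold_affirmed})
    rows = []
    for cui in cuis:
        tp = fp = fn = 0
        doc_ids = sorted({d for c, d in pred_affirmed if c == cui}
                         | {d for c, d in gold_affirmed if c == cui})
        for doc_id in doc_ids:
            preds = pred_affirmed.get((cui, doc_id), [])
            golds = gold_affirmed.get((cui, doc_id), [])
            adj = [
                [j for j, g in enumerate(golds)
                 if _spans_match(p, g, match_policy)]
                for p in preds
            ]
            matched = _max_matching(adj, len(golds))
            tp += matched
            fp += len(preds) - matched
            fn += len(golds) - matched
        rows.append(PRFRow(cui=cui, tp=tp, fp=fp, fn=fn))
    return PRFReport(tuple(rows))


# ---------------------------------------------------------------------------
# Outcome scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChecklistScore:
    n_items: int
    n_correct: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_items


def checklist_accuracy(responses: Sequence[Hashable],
                       reference: Sequence[Hashable]) -> ChecklistScore:
    """Mean per-criterion correctness against consensus reference answers.

    Each correct response earns one point; the score is the average over
    all criteria of the checklist (maximum 1).
    """
    if len(responses) != len(reference):
        raise MetricsError(
            f"response/reference length mismatch "
            f"({len(responses)} vs {len(reference)})")
    if not reference:
        raise MetricsError("empty checklist")
    n_correct = sum(1 for a, b in zip(responses, reference) if a == b)
    return ChecklistScore(n_items=len(reference), n_correct=n_correct)


_TLX_SUBSCALES = ("mental demand", "physical demand", "temporal demand",
                  "performance", "effort", "frustration")


def nasa_tlx_score(ratings: Sequence[float],
                   weights: Optional[Sequence[int]] = None) -> float:
    """Weighted NASA-TLX workload score on 0-100.

    ``ratings`` are the six subscale values on 0-20 (higher = more
    workload).  ``weights`` are the pairwise-comparison counts, six
    non-negative integers summing to 15.  When ``weights`` is omitted the
    unweighted "raw TLX" variant is computed (all subscales equal).  The
    weighted mean rating on 0-20 is scaled by 5 onto 0-100.
    """
    if len(ratings) != 6:
        raise MetricsError(f"expected 6 subscale ratings, got {len(ratings)}")
    for name, r in zip(_TLX_SUBSCALES, ratings):
        if not (0 <= r <= 20):
            raise MetricsError(f"{name} rating {r} outside [0, 20]")
    if weights is None:
        weighted_mean = sum(ratings) / 6.0
    else:
        if len(weights) != 6:
            raise MetricsError(f"expected 6 weights, got {len(weights)}")
        if any(w < 0 for w in weights):
            raise MetricsError("weights must be non-negative")
        if sum(weights) != 15:
            raise MetricsError(
                f"weights must sum to 15 (pairwise comparisons), "
                f"got {sum(weights)}")
        weighted_mean = sum(w * r for w, r in zip(weights, ratings)) / 15.0
    return weighted_mean * 5.0


def sus_score(responses: Sequence[int]) -> float:
    """Standard SUS usability score on 0-100.

    Ten Likert responses in 1..5; odd-numbered items (positively worded)
    contribute ``response - 1``, even-numbered items (negatively worded)
    contribute ``5 - response``; the sum of contributions is scaled by
    2.5.
    """
    if len(responses) != 10:
        raise MetricsError(f"expected 10 responses, got {len(responses)}")
    total = 0
    for i, r in enumerate(responses, start=1):
        if r not in (1, 2, 3, 4, 5):
            raise MetricsError(f"item {i} response {r!r} outside 1..5")
        total += (r - 1) if i % 2 == 1 else (5 - r)
    return total * 2.5
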