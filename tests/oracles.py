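"""Independent reference implementations used only as test oracles.

Everything here is written directly from the criterion definitions and
deliberately shares no code with the package:

* calendar window arithmetic is re-derived with ``calendar.monthrange``
  instead of dateutil;
* three-valued logic is expressed as min/max under the ordering
  NOT_MET < UNKNOWN < MET instead of explicit truth tables;
* span matching for precision/recall is solved by exhaustive subset
  enumeration instead of augmenting-path matching.
"""

from __future__ import annotations

import calendar
from datetime import timedelta

from trialscreen.inference import Status
from trialscreen.rules import Direction, LabMode, NodeKind, TimeUnit


# ---------------------------------------------------------------------------
# Windows (independent calendar arithmetic)
# ---------------------------------------------------------------------------

def shift_months_back(dt, months):
    total = dt.year * 12 + (dt.month - 1) - months
    year, month0 = divmod(total, 12)
    month = month0 + 1
    day = min(dt.day, calendar.monthrange(year, month)[1])
    return dt.replace(year=year, month=month, day=day)


def oracle_window_bounds(window, index_time):
    if window.unit is TimeUnit.DAYS:
        edge_back = index_time - timedelta(days=window.amount)
        edge_fwd = index_time + timedelta(days=window.amount)
    else:
        months = window.amount * (12 if window.unit is TimeUnit.YEARS else 1)
        edge_back = shift_months_back(index_time, months)
        edge_fwd = shift_months_back(index_time, -months)
    if window.direction is Direction.BEFORE_INDEX:
        return edge_back, index_time
    return index_time, edge_fwd


def oracle_in_window(ts, window, index_time):
    if window is None:
        return True
    start, end = oracle_window_bounds(window, index_time)
    return start <= ts < end


# ---------------------------------------------------------------------------
# Expression evaluation by enumeration
# ---------------------------------------------------------------------------

_ORDER = {Status.NOT_MET: 0, Status.UNKNOWN: 1, Status.MET: 2}
_BY_ORDER = {v: k for k, v in _ORDER.items()}


def oracle_eval(expr, record, annotations):
    """Evaluate a rule expression to a Status, straight from definitions."""
    if expr.kind is NodeKind.LAB:
        crit = expr.payload
        candidates = [
            (lab.timestamp, i, lab)
            for i, lab in enumerate(record.labs)
            if lab.item.code == crit.item.code
            and oracle_in_window(lab.timestamp, crit.window, record.index_time)
        ]
        if not candidates:
            return Status.UNKNOWN
        # most recent; timestamp ties broken by input order, last wins
        _, _, best = max(candidates, key=lambda t: (t[0], t[1]))
        if crit.mode is LabMode.RATIO_TO_CONTROL:
            if best.control_value is None:
                return Status.UNKNOWN
            observed = best.value / best.control_value
        else:
            observed = best.value
        sym = crit.comparator.value
        ok = {
            "LT": observed < crit.threshold,
            "LE": observed <= crit.threshold,
            "GT": observed > crit.threshold,
            "GE": observed >= crit.threshold,
            "EQ": observed == crit.threshold,
        }[sym]
        return Status.MET if ok else Status.NOT_MET
    if expr.kind is NodeKind.CONCEPT:
        crit = expr.payload
        wanted = {c.cui for c in crit.concepts}
        typed_docs = [d for d in record.documents if d.doc_type in crit.doc_types]
        if not typed_docs:
            return Status.UNKNOWN
        for doc in typed_docs:
            if not oracle_in_window(doc.timestamp, crit.window,
                                    record.index_time):
                continue
            for ann in annotations.get(doc.doc_id, []):
                if not ann.negated and ann.cui in wanted:
                    return Status.MET
        return Status.NOT_MET
    child = [oracle_eval(c, record, annotations) for c in expr.children]
    if expr.kind is NodeKind.NOT:
        return _BY_ORDER[2 - _ORDER[child[0]]]
    ranks = [_ORDER[s] for s in child]
    return _BY_ORDER[min(ranks) if expr.kind is NodeKind.AND else max(ranks)]


# ---------------------------------------------------------------------------
# Exhaustive PRF matching
# ---------------------------------------------------------------------------

def _overlap(a, b):
    return a[0] < b[1] and b[0] < a[1]


def oracle_prf_counts(pred_spans, gold_spans, policy="overlap"):
    """(tp, fp, fn) for one (CUI, document) group, by exhaustive search.

    Tries every injective assignment of predictions to gold items and
    keeps the one matching the most pairs.
    """
    match = (lambda p, g: p == g) if policy == "exact" else _overlap
    n_pred, n_gold = len(pred_spans), len(gold_spans)

    def best_from(i: int, used: frozenset) -> int:
        if i == n_pred:
            return 0
        best = best_from(i + 1, used)  # leave prediction i unmatched
        for j in range(n_gold):
            if j not in used and match(pred_spans[i], gold_spans[j]):
                best = max(best, 1 + best_from(i + 1, used | {j}))
        return best

    tp = best_from(0, frozenset())
    return tp, n_pred - tp, n_gold - tp
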