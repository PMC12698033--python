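"""Patient record bundles: timestamped clinical documents plus lab series.

A bundle on disk is a manifest (JSON) naming the patient, the index
time, and two data files: a JSONL stream of documents and a CSV lab
table.  Timestamps are ISO-8601; a date without a time component is
taken as midnight.  All temporal comparisons against eligibility windows
use the half-open convention documented on
:class:`~trialscreen.rules.TemporalWindow`.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Optional

import pandas as pd
from dateutil.relativedelta import relativedelta

from .rules import Direction, LabItem, TemporalWindow, TimeUnit


class BundleError(ValueError):
    """Malformed bundle content (bad line, duplicate id, bad timestamp)."""


@dataclass(frozen=True)
class ClinicalDocument:
    doc_id: str
    doc_type: str
    timestamp: datetime
    text: str


@dataclass(frozen=True)
class LabResult:
    item: LabItem
    value: float
    unit: str
    control_value: Optional[float]
    timestamp: datetime


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    index_time: datetime
    documents: tuple[ClinicalDocument, ...] = ()
    labs: tuple[LabResult, ...] = ()

    def document(self, doc_id: str) -> ClinicalDocument:
        for doc in self.documents:
            if doc.doc_id == doc_id:
                return doc
        raise KeyError(doc_id)


def parse_timestamp(raw: str, where: str = "") -> datetime:
    try:
        return datetime.fromisoformat(raw)
    except (TypeError, ValueError):
        suffix = f" ({where})" if where else ""
        raise BundleError(f"unparseable timestamp {raw!r}{suffix}") from None


# ---------------------------------------------------------------------------
# Temporal windows
# ---------------------------------------------------------------------------

def window_delta(window: TemporalWindow):
    if window.unit is TimeUnit.DAYS:
        return timedelta(days=window.amount)
    if window.unit is TimeUnit.MONTHS:
        return relativedelta(months=window.amount)
    return relativedelta(years=window.amount)


def resolve_window(window: TemporalWindow, index_time: datetime) -> tuple[datetime, datetime]:
    """Resolve a window to a concrete half-open interval ``[start, end)``.

    Month/year amounts are calendar steps with month-end clamping (e.g.
    one month before 31 March is 28/29 February), as provided by
    :class:`dateutil.relativedelta`.
    """
    delta = window_delta(window)
    if window.direction is Direction.BEFORE_INDEX:
        return index_time - delta, index_time
    return index_time, index_time + delta


def in_window(ts: datetime, window: Optional[TemporalWindow],
              index_time: datetime) -> bool:
    if window is None:
        return True
    start, end = resolve_window(window, index_time)
    return start <= ts < end


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def select_documents(record: PatientRecord, doc_types: Iterable[str],
                     window: Optional[TemporalWindow] = None) -> list[ClinicalDocument]:
    """Documents of the requested types, optionally window-filtered.

    Pure filter, ordered by (timestamp, doc_id) for stable output.
    """
    wanted = set(doc_types)
    hits = [
        d for d in record.documents
        if d.doc_type in wanted and in_window(d.timestamp, window, record.index_time)
    ]
    hits.sort(key=lambda d: (d.timestamp, d.doc_id))
    return hits


def latest_lab(record: PatientRecord, item_code: str,
               window: Optional[TemporalWindow] = None) -> Optional[LabResult]:
    """Most recent in-window result for a lab item, or ``None``.

    Timestamp ties are broken by input order (last wins), matching the
    convention that a corrected re-entry supersedes the original row.
    """
    best: Optional[LabResult] = None
    for lab in record.labs:
        if lab.item.code != item_code:
            continue
        if not in_window(lab.timestamp, window, record.index_time):
            continue
        if best is None or lab.timestamp >= best.timestamp:
            best = lab
    return best


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

_LAB_COLUMNS = ["item_code", "item_name", "value", "unit", "control_value",
                "timestamp"]


def _docs_from_jsonl(path) -> tuple[ClinicalDocument, ...]:
    docs: list[ClinicalDocument] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise BundleError(
                    f"{path}:{lineno}: malformed document line: {exc}") from exc
            try:
                doc_id = str(obj["doc_id"])
                doc = ClinicalDocument(
                    doc_id=doc_id,
                    doc_type=str(obj["doc_type"]),
                    timestamp=parse_timestamp(obj["timestamp"],
                                              f"{path}:{lineno}"),
                    text=str(obj["text"]),
                )
            except KeyError as exc:
                raise BundleError(
                    f"{path}:{lineno}: missing document field {exc}") from exc
            if doc_id in seen:
                raise BundleError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            docs.append(doc)
    return tuple(docs)


def _labs_from_csv(path) -> tuple[LabResult, ...]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _LAB_COLUMNS if c not in frame.columns]
    if missing:
        raise BundleError(f"{path}: lab table missing column(s) {missing}")
    labs: list[LabResult] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            value = float(row.value)
        except ValueError:
            raise BundleError(f"{path}:{i}: non-numeric lab value "
                              f"{row.value!r}") from None
        if not math.isfinite(value):
            raise BundleError(f"{path}:{i}: lab value must be finite")
        control: Optional[float] = None
        if row.control_value != "":
            try:
                control = float(row.control_value)
            except ValueError:
                raise BundleError(f"{path}:{i}: non-numeric control value "
                                  f"{row.control_value!r}") from None
            if not (control > 0):
                raise BundleError(f"{path}:{i}: control value must be > 0")
        labs.append(LabResult(
            item=LabItem(code=row.item_code, name=row.item_name),
            value=value,
            unit=row.unit,
            control_value=control,
            timestamp=parse_timestamp(row.timestamp, f"{path}:{i}"),
        ))
    return tuple(labs)


def read_bundle(manifest_path) -> PatientRecord:
    """Load a patient bundle from its manifest file."""
    with open(manifest_path, encoding="utf-8") as fh:
        try:
            manifest = json.load(fh)
        except json.JSONDecodeError as exc:
            raise BundleError(f"{manifest_path}: malformed manifest: {exc}") from exc
    for key in ("patient_id", "index_time", "documents_file", "labs_file"):
        if key not in manifest:
            raise BundleError(f"{manifest_path}: manifest missing {key!r}")
    if not str(manifest["patient_id"]):
        raise BundleError(f"{manifest_path}: patient_id must be non-empty")
    base = os.path.dirname(os.fspath(manifest_path))
    return PatientRecord(
        patient_id=str(manifest["patient_id"]),
        index_time=parse_timestamp(manifest["index_time"], str(manifest_path)),
        documents=_docs_from_jsonl(os.path.join(base, manifest["documents_file"])),
        labs=_labs_from_csv(os.path.join(base, manifest["labs_file"])),
    )


def write_bundle(record: PatientRecord, manifest_path) -> None:
    """Write a patient bundle (manifest + documents JSONL + labs CSV)."""
    base = os.path.dirname(os.fspath(manifest_path))
    os.makedirs(base or ".", exist_ok=True)
    stem = os.path.splitext(os.path.basename(os.fspath(manifest_path)))[0]
    docs_name = f"{stem}.documents.jsonl"
    labs_name = f"{stem}.labs.csv"
    with open(os.path.join(base, docs_name), "w", encoding="utf-8") as fh:
        for doc in record.documents:
            fh.write(json.dumps({
                "doc_id": doc.doc_id,
                "doc_type": doc.doc_type,
                "timestamp": doc.timestamp.isoformat(),
                "text": doc.text,
            }, ensure_ascii=False) + "\n")
    frame = pd.DataFrame(
        [
            {
                "item_code": lab.item.code,
                "item_name": lab.item.name,
                "value": lab.value,
                "unit": lab.unit,
                "control_value": "" if lab.control_value is None else lab.control_value,
                "timestamp": lab.timestamp.isoformat(),
            }
            for lab in record.labs
        ],
        columns=_LAB_COLUMNS,
    )
    frame.to_csv(os.path.join(base, labs_name), index=False)
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump({
            "patient_id": record.patient_id,
            "index_time": record.index_time.isoformat(),
            "documents_file": docs_name,
            "labs_file": labs_name,
        }, fh, indent=2)
        fh.write("\n")
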