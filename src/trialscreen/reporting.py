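"""Static screening reports: checklist table, flagged documents, highlights.

The report mirrors a reviewer's two-panel screen: a per-criterion verdict
table (role and status stated side by side; UNKNOWN is rendered as
"needs review"), the list of documents carrying evidence (the "red dot"
set), and each document body with concept mentions highlighted.  Affirmed
and negated mentions are styled differently, and the legend says so.
Output is deterministic byte-for-byte for fixed input.
"""

from __future__ import annotations

import html
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .emr import ClinicalDocument, PatientRecord
from .inference import AnnotationEvidence, ScreeningResult, Status, result_to_json
from .tagger import ConceptAnnotation


class ReportError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    text: str
    highlighted: bool
    annotation: Optional[ConceptAnnotation] = None


@dataclass(frozen=True)
class HighlightedDocument:
    doc_id: str
    segments: tuple[Segment, ...]

    @property
    def text(self) -> str:
        return "".join(s.text for s in self.segments)


def highlight_document(doc: ClinicalDocument,
                       annotations: Sequence[ConceptAnnotation]
                       ) -> HighlightedDocument:
    """Partition a document's text into plain and highlighted segments.

    The concatenation of segment texts equals the original text exactly;
    every annotation span becomes one highlighted segment.  Overlapping
    or out-of-range spans are rejected.
    """
    ordered = sorted(annotations, key=lambda a: (a.start, a.end))
    segments: list[Segment] = []
    cursor = 0
    for ann in ordered:
        if ann.doc_id != doc.doc_id:
            raise ReportError(
                f"annotation for {ann.doc_id!r} applied to {doc.doc_id!r}")
        if ann.start < cursor:
            raise ReportError(
                f"overlapping annotation spans at {ann.span} in {doc.doc_id}")
        if ann.end > len(doc.text) or ann.start > ann.end:
            raise ReportError(
                f"annotation span {ann.span} outside document {doc.doc_id}")
        if ann.start > cursor:
            segments.append(Segment(doc.text[cursor:ann.start], False))
        segments.append(Segment(doc.text[ann.start:ann.end], True, ann))
        cursor = ann.end
    if cursor < len(doc.text):
        segments.append(Segment(doc.text[cursor:], False))
    if not segments:
        segments.append(Segment(doc.text, False))
    return HighlightedDocument(doc_id=doc.doc_id, segments=tuple(segments))


_STATUS_DISPLAY = {
    Status.MET: "yes",
    Status.NOT_MET: "no",
    Status.UNKNOWN: "no (needs review)",
}


def _check_evidence(result: ScreeningResult, record: PatientRecord) -> None:
    doc_ids = {d.doc_id for d in record.documents}
    for v in result.verdicts:
        for ev in v.evidence:
            if isinstance(ev, AnnotationEvidence) and ev.doc_id not in doc_ids:
                raise ReportError(
                    f"verdict {v.criterion_label!r} cites unknown document "
                    f"{ev.doc_id!r}")
    for doc_id in result.relevant_docs:
        if doc_id not in doc_ids:
            raise ReportError(f"relevant document {doc_id!r} not in record")


def render_markdown(result: ScreeningResult, record: PatientRecord,
                    highlights: Mapping[str, HighlightedDocument]) -> str:
    """Render the screening result as Markdown."""
    _check_evidence(result, record)
    lines = [
        f"# Eligibility screening: {result.trial_name} "
        f"(v{result.checklist_version})",
        "",
        f"Patient: `{result.patient_id}`  ",
        f"Index time: {record.index_time.isoformat()}",
        "",
        "## Checklist",
        "",
        "| # | Criterion | Role | Answer | Basis |",
        "|---|-----------|------|--------|-------|",
    ]
    for i, v in enumerate(result.verdicts, start=1):
        basis = v.explanation.replace("|", "\\|")
        lines.append(
            f"| {i} | {v.criterion_label} | {v.role.value.lower()} | "
            f"{_STATUS_DISPLAY[v.status]} | {basis} |")
    lines += ["", "## Documents", ""]
    for doc in record.documents:
        flag = "● relevant" if doc.doc_id in result.relevant_docs else ""
        lines.append(f"- `{doc.doc_id}` ({doc.doc_type}, "
                     f"{doc.timestamp.isoformat()}) {flag}".rstrip())
    lines += ["", "## Document bodies",
              "",
              "Highlighted mentions: **affirmed** are bold, "
              "~~negated~~ are struck through.", ""]
    for doc in record.documents:
        hl = highlights.get(doc.doc_id)
        lines.append(f"### {doc.doc_id} ({doc.doc_type})")
        lines.append("")
        if hl is None:
            lines.append(doc.text)
        else:
            parts = []
            for seg in hl.segments:
                if not seg.highlighted:
                    parts.append(seg.text)
                elif seg.annotation is not None and seg.annotation.negated:
                    parts.append(f"~~{seg.text}~~")
                else:
                    parts.append(f"**{seg.text}**")
            lines.append("".join(parts))
        lines.append("")
    return "\n".join(lines)


_HTML_CSS = """
body { font-family: sans-serif; margin: 2em; max-width: 60em; }
table { border-collapse: collapse; }
td, th { border: 1px solid #999; padding: 0.3em 0.6em; }
.met { background: #d9f2d9; }
.not_met { background: #f2d9d9; }
.unknown { background: #f2ecd9; }
.dot { color: #c00; }
mark.affirmed { background: #ffe066; }
mark.negated { background: #d0d0d0; text-decoration: line-through; }
pre.doc { white-space: pre-wrap; border: 1px solid #ccc; padding: 1em; }
"""


def render_html(result: ScreeningResult, record: PatientRecord,
                highlights: Mapping[str, HighlightedDocument]) -> str:
    """Render a self-contained HTML report with checklist-to-evidence anchors."""
    _check_evidence(result, record)
    esc = html.escape
    out = [
        "<!DOCTYPE html>",
        "<html><head><meta charset=\"utf-8\">",
        f"<title>{esc(result.trial_name)} — {esc(result.patient_id)}</title>",
        f"<style>{_HTML_CSS}</style></head><body>",
        f"<h1>Eligibility screening: {esc(result.trial_name)} "
        f"(v{esc(result.checklist_version)})</h1>",
        f"<p>Patient <code>{esc(result.patient_id)}</code>, "
        f"index time {esc(record.index_time.isoformat())}</p>",
        "<h2>Checklist</h2>",
        "<table><tr><th>#</th><th>Criterion</th><th>Role</th>"
        "<th>Answer</th><th>Evidence</th></tr>",
    ]
    for i, v in enumerate(result.verdicts, start=1):
        links = []
        for ev in v.evidence:
            if isinstance(ev, AnnotationEvidence):
                anchor = f"ann-{ev.doc_id}-{ev.start}"
                links.append(f'<a href="#{anchor}">{esc(ev.matched_text)}'
                             f' [{esc(ev.doc_id)}]</a>')
            else:
                links.append(f"{esc(ev.item_code)}={ev.value:g} "
                             f"@ {esc(ev.timestamp)}")
        out.append(
            f'<tr class="{v.status.value.lower()}"><td>{i}</td>'
            f"<td>{esc(v.criterion_label)}</td>"
            f"<td>{esc(v.role.value.lower())}</td>"
            f"<td>{esc(_STATUS_DISPLAY[v.status])}</td>"
            f"<td>{'; '.join(links)}</td></tr>")
    out.append("</table>")
    out.append("<h2>Documents</h2><ul>")
    for doc in record.documents:
        dot = ' <span class="dot">&#9679;</span> relevant' \
            if doc.doc_id in result.relevant_docs else ""
        out.append(f'<li><a href="#doc-{esc(doc.doc_id)}">'
                   f"<code>{esc(doc.doc_id)}</code></a> "
                   f"({esc(doc.doc_type)}, {esc(doc.timestamp.isoformat())})"
                   f"{dot}</li>")
    out.append("</ul>")
    out.append("<h2>Document bodies</h2>")
    out.append("<p>Legend: <mark class=\"affirmed\">affirmed mention</mark>, "
               "<mark class=\"negated\">negated mention</mark> — negated "
               "mentions are shown for audit but carry no evidential "
               "weight.</p>")
    for doc in record.documents:
        out.append(f'<h3 id="doc-{esc(doc.doc_id)}">{esc(doc.doc_id)} '
                   f"({esc(doc.doc_type)})</h3>")
        hl = highlights.get(doc.doc_id)
        if hl is None:
            out.append(f'<pre class="doc">{esc(doc.text)}</pre>')
            continue
        parts = ['<pre class="doc">']
        for seg in hl.segments:
            if not seg.highlighted:
                parts.append(esc(seg.text))
            else:
                ann = seg.annotation
                cls = "negated" if ann is not None and ann.negated else "affirmed"
                anchor = f"ann-{doc.doc_id}-{ann.start}" if ann else ""
                parts.append(f'<mark class="{cls}" id="{esc(anchor)}">'
                             f"{esc(seg.text)}</mark>")
        parts.append("</pre>")
        out.append("".join(parts))
    out.append("</body></html>")
    return "\n".join(out) + "\n"


def render_report(result: ScreeningResult, record: PatientRecord,
                  annotations: Mapping[str, Sequence[ConceptAnnotation]],
                  out_dir, formats: Iterable[str] = ("json", "md", "html")
                  ) -> dict[str, str]:
    """Write the machine-readable result plus human-readable report files.

    Returns a mapping of format name to written path.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    highlights = {
        doc.doc_id: highlight_document(doc, annotations.get(doc.doc_id, ()))
        for doc in record.documents
    }
    written: dict[str, str] = {}
    formats = set(formats)
    if "json" in formats:
        path = os.path.join(out_dir, f"{result.patient_id}.result.json")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(result_to_json(result))
        written["json"] = path
    if "md" in formats:
        path = os.path.join(out_dir, f"{result.patient_id}.report.md")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(render_markdown(result, record, highlights))
        written["md"] = path
    if "html" in formats:
        path = os.path.join(out_dir, f"{result.patient_id}.report.html")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(render_html(result, record, highlights))
        written["html"] = path
    return written
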