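"""Deterministic synthetic patient bundles with known ground truth.

The generator emulates the setting the screening tool is built for:
multi-department note streams per stroke patient (admission, outpatient,
discharge, nursing, radiology), criteria-relevant concept mentions
planted affirmatively or under negation, distractor mentions of the same
surface forms in places where no criterion can qualify them, and lab
series including ratio-to-control items.  Critical facts can be buried
in the least prominent stream (outpatient notes).

Everything needed to test the pipeline end-to-end comes out of one call:
the patient record, the lexicon covering exactly the planted forms, the
gold span annotations, and the expected per-criterion verdict statuses.
Expected verdicts are computed *at generation time* from the planted
facts, labs, and document inventory by a small evaluator private to this
module — never by running the inference engine, which the expectations
exist to check.

Three construction rules keep the ground truth exact:

* one deliberately planted fact per document, so a negation trigger can
  never scope onto a neighbouring planted mention;
* narrative boilerplate contains no lexicon surface form and no negation
  trigger or terminator token (asserted at generation time);
* a distractor mention is only planted at a (document type, timestamp)
  position where every criterion referencing its concept is blocked by
  the document-type filter or the temporal window.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from datetime import datetime, timedelta
from importlib import resources
from typing import Optional, Sequence

from .dsl import parse_dsl
from .emr import ClinicalDocument, LabResult, PatientRecord, in_window
from .inference import Status, kleene_and, kleene_not, kleene_or
from .metrics import GoldAnnotationSet, GoldItem
from .rules import Checklist, LabItem, LabMode, NodeKind, RuleExpr
from .tagger import (
    Lexicon,
    LexiconEntry,
    NegationRuleSet,
    SurfaceForm,
    default_negation_rules,
    tokenize,
)

INDEX_TIME = datetime(2024, 6, 15, 9, 30)

DOC_TYPES = ("admission note", "outpatient note", "discharge summary",
             "nursing note", "radiology report")


def default_lexicon() -> Lexicon:
    """The synthetic stroke-screening lexicon shipped with the generator.

    Concept identifiers follow the CUI convention; the entries are a
    small self-contained demo vocabulary, not an excerpt of any licensed
    terminology.  The Anticoagulant entry models a broad drug class as
    one concept with enumerated member-drug surface forms.
    """
    e = LexiconEntry
    f = SurfaceForm
    return Lexicon((
        e("C0018674", "Head injury", ("dsyn",),
          (f("head injury"), f("head trauma"), f("cranial trauma"))),
        e("C0018681", "Headache", ("sosy",),
          (f("headache"), f("cephalalgia"))),
        e("C0011849", "Diabetes mellitus", ("dsyn",),
          (f("diabetes mellitus"), f("diabetes"), f("type 2 diabetes"))),
        e("C0038454", "Prior stroke", ("dsyn",),
          (f("stroke"), f("cerebral infarction"), f("ischemic stroke"),
           f("CVA", case_sensitive=True))),
        e("C0021843", "Internal bleeding", ("dsyn",),
          (f("internal bleeding"), f("gastrointestinal bleeding"),
           f("GI bleeding"), f("hematochezia"))),
        e("C0003280", "Anticoagulant", ("phsu",),
          (f("anticoagulant"), f("warfarin"), f("apixaban"),
           f("dabigatran"), f("edoxaban"), f("rivaroxaban"))),
        e("C0151699", "Intracranial hemorrhage", ("dsyn",),
          (f("intracranial hemorrhage"), f("brain hemorrhage"),
           f("ICH", case_sensitive=True))),
        e("C0036572", "Seizure", ("dsyn",),
          (f("seizure"), f("convulsion"))),
        e("C0038895", "Major surgery", ("topp",),
          (f("major surgery"), f("surgical operation"), f("laparotomy"))),
        e("C0027051", "Myocardial infarction", ("dsyn",),
          (f("myocardial infarction"), f("heart attack"),
           f("MI", case_sensitive=True))),
    ))


def default_checklist(lexicon: Optional[Lexicon] = None) -> Checklist:
    """The eleven-item thrombolysis-style checklist fixture."""
    if lexicon is None:
        lexicon = default_lexicon()
    ref = resources.files("trialscreen").joinpath("data/rtpa_checklist.dsl")
    return parse_dsl(ref.read_text(encoding="utf-8"), lexicon=lexicon)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedFact:
    """A concept mention to embed in one generated document."""
    cui: str
    polarity: str  # "affirmed" | "negated"
    days_before_index: float
    doc_type: Optional[str] = None  # None -> drawn from the type mix


@dataclass(frozen=True)
class LabPoint:
    days_before_index: float
    value: float
    control_value: Optional[float] = None


@dataclass(frozen=True)
class LabSeries:
    item_code: str
    item_name: str
    unit: str
    points: tuple[LabPoint, ...]


@dataclass(frozen=True)
class GenerationProfile:
    seed: int
    n_documents: int = 8
    doc_type_mix: tuple[tuple[str, float], ...] = (
        ("admission note", 0.30),
        ("outpatient note", 0.30),
        ("discharge summary", 0.20),
        ("nursing note", 0.20),
    )
    planted_facts: tuple[PlantedFact, ...] = ()
    distractor_density: float = 1.0
    lab_series: tuple[LabSeries, ...] = ()
    bury_in_outpatient: bool = False


@dataclass(frozen=True)
class GroundTruthBundle:
    record: PatientRecord
    lexicon: Lexicon
    gold: GoldAnnotationSet
    expected_verdicts: tuple[Status, ...]
    checklist: Checklist


# ---------------------------------------------------------------------------
# Narrative templates
# ---------------------------------------------------------------------------

_BOILERPLATE = {
    "admission note": (
        "Admitted for evaluation of sudden weakness.",
        "Vitals stable on arrival.",
        "Neurological examination documented in full.",
        "Family at bedside during assessment.",
    ),
    "outpatient note": (
        "Routine clinic visit today.",
        "Medication list reviewed with the patient.",
        "Follow-up in three months arranged.",
        "Lifestyle counselling provided.",
    ),
    "discharge summary": (
        "Hospital course uncomplicated.",
        "Discharged home in stable condition.",
        "Written instructions given at departure.",
        "Primary care physician informed.",
    ),
    "nursing note": (
        "Vital signs recorded per protocol.",
        "Patient resting comfortably.",
        "Call bell within reach.",
        "Intake and output charted.",
    ),
    "radiology report": (
        "Imaging study performed as requested.",
        "Technical quality adequate.",
        "Comparison made with earlier studies.",
        "Findings communicated to the ordering team.",
    ),
}

_AFFIRMED_TEMPLATES = (
    "History of {} documented.",
    "The patient reports {} on direct questioning.",
    "Past medical record shows {}.",
    "Problem list includes {}.",
)

# Each opens with a pre-trigger from the shipped negation rule set and
# places the mention directly inside the trigger scope.
_NEGATED_TEMPLATES = (
    "No history of {} per the patient.",
    "Denies {} at this visit.",
    "No evidence of {} on review.",
    "Negative for {} today.",
)

_DISTRACTOR_TEMPLATES = (
    "Chart review shows {} in earlier records.",
    "Referral letter mentions {}.",
    "Prior documentation describes {}.",
)


def _check_templates(lexicon: Lexicon, rules: NegationRuleSet) -> None:
    """Guard: template prose must stay inert under tagging and negation."""
    forms = {
        tuple(t.casefold() for _, _, t in tokenize(f.text))
        for e in lexicon.entries for f in e.surface_forms
    }
    triggers = {
        tuple(t.casefold() for _, _, t in tokenize(trig))
        for trig in rules.pre_triggers + rules.post_triggers
    }
    terminators = {t.casefold() for t in rules.terminators}
    prose = [s for sentences in _BOILERPLATE.values() for s in sentences]
    prose += [t.replace("{}", " ") for t in
              _AFFIRMED_TEMPLATES + _DISTRACTOR_TEMPLATES]
    max_n = max(len(k) for k in forms | triggers)
    for s in prose:
        toks = [t.casefold() for _, _, t in tokenize(s)]
        if set(toks) & terminators:
            raise AssertionError(f"template contains terminator token: {s!r}")
        for n in range(1, max_n + 1):
            for i in range(len(toks) - n + 1):
                gram = tuple(toks[i:i + n])
                if gram in forms:
                    raise AssertionError(f"template contains lexicon form: {s!r}")
                if gram in triggers:
                    raise AssertionError(f"template contains trigger: {s!r}")


# ---------------------------------------------------------------------------
# Expected-verdict evaluator (generation-time, engine-independent)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Fact:
    cui: str
    negated: bool
    doc_type: str
    timestamp: datetime


def _expected_status(expr: RuleExpr, facts: Sequence[_Fact],
                     doc_inventory: Sequence[tuple[str, datetime]],
                     labs: Sequence[LabResult], index_time: datetime) -> Status:
    if expr.kind is NodeKind.LAB:
        crit = expr.payload
        best: Optional[LabResult] = None
        for lab in labs:
            if lab.item.code != crit.item.code:
                continue
            if not in_window(lab.timestamp, crit.window, index_time):
                continue
            if best is None or lab.timestamp >= best.timestamp:
                best = lab
        if best is None:
            return Status.UNKNOWN
        if crit.mode is LabMode.RATIO_TO_CONTROL:
            if best.control_value is None:
                return Status.UNKNOWN
            observed = best.value / best.control_value
        else:
            observed = best.value
        return (Status.MET if crit.comparator.apply(observed, crit.threshold)
                else Status.NOT_MET)
    if expr.kind is NodeKind.CONCEPT:
        crit = expr.payload
        if not any(t in crit.doc_types for t, _ in doc_inventory):
            return Status.UNKNOWN
        wanted = {c.cui for c in crit.concepts}
        for fact in facts:
            if fact.negated or fact.cui not in wanted:
                continue
            if fact.doc_type not in crit.doc_types:
                continue
            if in_window(fact.timestamp, crit.window, index_time):
                return Status.MET
        return Status.NOT_MET
    child = [_expected_status(c, facts, doc_inventory, labs, index_time)
             for c in expr.children]
    if expr.kind is NodeKind.NOT:
        return kleene_not(child[0])
    return kleene_and(child) if expr.kind is NodeKind.AND else kleene_or(child)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _criteria_for_cui(checklist: Checklist, cui: str):
    out = []
    for item in checklist.items:
        for _, node in item.expr.walk():
            if node.kind is NodeKind.CONCEPT and any(
                    c.cui == cui for c in node.payload.concepts):
                out.append(node.payload)
    return out


def _distractor_safe(checklist: Checklist, cui: str, doc_type: str,
                     ts: datetime, index_time: datetime) -> bool:
    """True when no criterion could count a mention at this position."""
    for crit in _criteria_for_cui(checklist, cui):
        if doc_type in crit.doc_types and in_window(ts, crit.window, index_time):
            return False
    return True


# a sentence carrying one mention: (text, form offset, form length, cui, negated)
_Planted = tuple[str, int, int, str, bool]


def _render(template: str, form: str, cui: str, negated: bool) -> _Planted:
    head, tail = template.split("{}")
    return head + form + tail, len(head), len(form), cui, negated


def generate_patient(profile: GenerationProfile,
                     checklist: Optional[Checklist] = None,
                     lexicon: Optional[Lexicon] = None,
                     rules: Optional[NegationRuleSet] = None,
                     patient_id: Optional[str] = None) -> GroundTruthBundle:
    """Generate one patient bundle with exact ground truth.

    Identical inputs produce an identical bundle, byte for byte once
    written to disk.
    """
    if lexicon is None:
        lexicon = default_lexicon()
    if checklist is None:
        checklist = default_checklist(lexicon)
    if rules is None:
        rules = default_negation_rules()
    _check_templates(lexicon, rules)
    rng = random.Random(profile.seed)
    index_time = INDEX_TIME
    patient_id = patient_id or f"P{profile.seed:06d}"

    type_labels = [t for t, _ in profile.doc_type_mix]
    type_weights = [w for _, w in profile.doc_type_mix]

    documents: list[ClinicalDocument] = []
    gold_items: list[GoldItem] = []
    facts: list[_Fact] = []

    def build_doc(doc_type: str, ts: datetime,
                  planted: Sequence[_Planted]) -> None:
        doc_id = f"{patient_id}-d{len(documents) + 1:03d}"
        parts: list[tuple[str, Optional[_Planted]]] = [
            (s, None)
            for s in rng.sample(_BOILERPLATE[doc_type], k=rng.randint(2, 3))
        ]
        for p in planted:
            parts.insert(rng.randint(0, len(parts)), (p[0], p))
        text = ""
        for sentence, p in parts:
            offset = len(text)
            text += sentence + " "
            if p is not None:
                _, local, flen, cui, negated = p
                gold_items.append(GoldItem(doc_id, offset + local,
                                           offset + local + flen,
                                           cui, negated))
        documents.append(ClinicalDocument(doc_id, doc_type, ts, text.rstrip()))

    # --- one document per deliberately planted fact ---
    for fact in profile.planted_facts:
        entry = lexicon.entry(fact.cui)
        if entry is None:
            raise ValueError(f"planted fact references unknown CUI {fact.cui!r}")
        doc_type = fact.doc_type
        if doc_type is None:
            doc_type = ("outpatient note" if profile.bury_in_outpatient
                        else rng.choices(type_labels, type_weights)[0])
        ts = index_time - timedelta(days=fact.days_before_index)
        form = rng.choice(entry.surface_forms).text
        negated = fact.polarity == "negated"
        template = rng.choice(_NEGATED_TEMPLATES if negated
                              else _AFFIRMED_TEMPLATES)
        build_doc(doc_type, ts, [_render(template, form, fact.cui, negated)])
        facts.append(_Fact(fact.cui, negated, doc_type, ts))

    # --- filler documents carrying only safe distractor mentions ---
    while len(documents) < profile.n_documents:
        doc_type = rng.choices(type_labels, type_weights)[0]
        ts = index_time - timedelta(days=rng.uniform(1.0, 1400.0))
        planted: list[_Planted] = []
        if profile.distractor_density > 0:
            whole = int(profile.distractor_density)
            frac = profile.distractor_density - whole
            k = min(3, whole + (1 if rng.random() < frac else 0))
            safe = [e for e in lexicon.entries
                    if _distractor_safe(checklist, e.cui, doc_type, ts,
                                        index_time)]
            for _ in range(k):
                if not safe:
                    break
                entry = rng.choice(safe)
                form = rng.choice(entry.surface_forms).text
                template = rng.choice(_DISTRACTOR_TEMPLATES)
                planted.append(_render(template, form, entry.cui, False))
                facts.append(_Fact(entry.cui, False, doc_type, ts))
        build_doc(doc_type, ts, planted)

    labs = tuple(
        LabResult(
            item=LabItem(code=series.item_code, name=series.item_name),
            value=point.value,
            unit=series.unit,
            control_value=point.control_value,
            timestamp=index_time - timedelta(days=point.days_before_index),
        )
        for series in profile.lab_series
        for point in series.points
    )
    record = PatientRecord(patient_id=patient_id, index_time=index_time,
                           documents=tuple(documents), labs=labs)
    inventory = [(d.doc_type, d.timestamp) for d in documents]
    expected = tuple(
        _expected_status(item.expr, facts, inventory, labs, index_time)
        for item in checklist.items
    )
    return GroundTruthBundle(record=record, lexicon=lexicon,
                             gold=GoldAnnotationSet(tuple(gold_items)),
                             expected_verdicts=expected, checklist=checklist)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

_STANDARD_LABS = (
    ("PLT", "Platelet count", "10*3/uL"),
    ("APTT", "Activated partial thromboplastin time", "s"),
    ("GLU", "Blood glucose", "mg/dL"),
)


def _random_lab_series(rng: random.Random) -> tuple[LabSeries, ...]:
    series = []
    # platelets: always present, occasionally below the 100k threshold
    series.append(LabSeries("PLT", "Platelet count", "10*3/uL", (
        LabPoint(rng.uniform(0.1, 3.0), rng.choice(
            [rng.uniform(60_000, 99_000), rng.uniform(110_000, 320_000),
             rng.uniform(110_000, 320_000)])),
    )))
    # APTT: sometimes out of window, sometimes missing its control value
    points = [LabPoint(rng.uniform(0.1, 10.0), rng.uniform(25.0, 70.0),
                       None if rng.random() < 0.2 else 30.0)]
    if rng.random() < 0.5:
        points.append(LabPoint(rng.uniform(10.0, 40.0),
                               rng.uniform(25.0, 70.0), 30.0))
    series.append(LabSeries("APTT", "Activated partial thromboplastin time",
                            "s", tuple(points)))
    # glucose: sometimes absent entirely (-> UNKNOWN for that item)
    if rng.random() < 0.7:
        series.append(LabSeries("GLU", "Blood glucose", "mg/dL", (
            LabPoint(rng.uniform(0.1, 2.0), rng.uniform(40.0, 220.0)),
        )))
    return tuple(series)


def _random_profile(seed: int, checklist: Checklist,
                    lexicon: Lexicon) -> GenerationProfile:
    """A varied patient: random subset of criteria satisfied or negated."""
    rng = random.Random(seed)
    concept_cuis = sorted({
        c.cui
        for item in checklist.items
        for _, node in item.expr.walk()
        if node.kind is NodeKind.CONCEPT
        for c in node.payload.concepts
    })
    facts: list[PlantedFact] = []
    for cui in concept_cuis:
        roll = rng.random()
        if roll < 0.30:
            polarity = "affirmed"
        elif roll < 0.45:
            polarity = "negated"
        else:
            continue
        crits = _criteria_for_cui(checklist, cui)
        crit = rng.choice(crits)
        doc_type = rng.choice(sorted(crit.doc_types) + ["nursing note"])
        if crit.window is not None and rng.random() < 0.7:
            # usually inside the window of the chosen criterion
            horizon = {"DAYS": 1.0, "MONTHS": 30.0,
                       "YEARS": 365.0}[crit.window.unit.value]
            days = rng.uniform(0.1, max(0.2, crit.window.amount * horizon * 0.9))
        else:
            days = rng.uniform(1.0, 1400.0)
        facts.append(PlantedFact(cui, polarity, days, doc_type))
    n_documents = max(8, len(facts) + rng.randint(2, 4))
    return GenerationProfile(
        seed=rng.randrange(2**31),
        n_documents=n_documents,
        planted_facts=tuple(facts),
        distractor_density=rng.uniform(0.5, 1.5),
        lab_series=_random_lab_series(rng),
    )


def challenge_profiles(seed: int) -> tuple[GenerationProfile, ...]:
    """Four hard cases patterned on realistic screening pitfalls.

    1. An anticoagulant exposure documented only in an outpatient note;
    2. an APTT exactly at the ratio-to-control boundary (latest-in-window
       selection matters: an older, higher value sits just outside);
    3. a diabetes/prior-stroke conjunction split across two documents of
       different departments;
    4. a patient whose record contains only negated mentions and no labs.
    """
    rng = random.Random(seed)
    s = [rng.randrange(2**31) for _ in range(4)]
    common_labs = (
        LabSeries("PLT", "Platelet count", "10*3/uL",
                  (LabPoint(0.5, 210_000.0),)),
        LabSeries("GLU", "Blood glucose", "mg/dL", (LabPoint(0.5, 112.0),)),
    )
    buried = GenerationProfile(
        seed=s[0], n_documents=10,
        planted_facts=(PlantedFact("C0003280", "affirmed", 1.0,
                                   "outpatient note"),),
        bury_in_outpatient=True,
        lab_series=common_labs + (
            LabSeries("APTT", "Activated partial thromboplastin time", "s",
                      (LabPoint(2.0, 33.0, 30.0),)),),
    )
    ratio_boundary = GenerationProfile(
        seed=s[1], n_documents=8,
        planted_facts=(PlantedFact("C0018681", "negated", 30.0,
                                   "outpatient note"),),
        lab_series=common_labs + (
            LabSeries("APTT", "Activated partial thromboplastin time", "s", (
                LabPoint(9.0, 60.0, 30.0),   # outside the 7-day window
                LabPoint(3.0, 42.0, 30.0),   # ratio exactly 1.4 -> MET under <=
            )),),
    )
    conjunction = GenerationProfile(
        seed=s[2], n_documents=10,
        planted_facts=(
            PlantedFact("C0011849", "affirmed", 400.0, "outpatient note"),
            PlantedFact("C0038454", "affirmed", 700.0, "discharge summary"),
        ),
        lab_series=common_labs + (
            LabSeries("APTT", "Activated partial thromboplastin time", "s",
                      (LabPoint(2.0, 35.0, 30.0),)),),
    )
    negated_only = GenerationProfile(
        seed=s[3], n_documents=8,
        planted_facts=(
            PlantedFact("C0018674", "negated", 200.0, "admission note"),
            PlantedFact("C0151699", "negated", 90.0, "discharge summary"),
            PlantedFact("C0003280", "negated", 1.0, "admission note"),
        ),
        lab_series=(),  # all lab items UNKNOWN
    )
    return (buried, ratio_boundary, conjunction, negated_only)


def generate_cohort(n: int, base_seed: int = 0,
                    checklist: Optional[Checklist] = None,
                    lexicon: Optional[Lexicon] = None,
                    rules: Optional[NegationRuleSet] = None,
                    include_challenges: bool = True
                    ) -> list[GroundTruthBundle]:
    """Generate ``n`` independent patient bundles.

    When ``include_challenges`` is true and ``n >= 4``, the first four
    patients are the :func:`challenge_profiles` hard cases; the rest are
    randomized profiles with per-patient seeds derived from
    ``base_seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if lexicon is None:
        lexicon = default_lexicon()
    if checklist is None:
        checklist = default_checklist(lexicon)
    master = random.Random(base_seed)
    profiles: list[GenerationProfile] = []
    if include_challenges and n >= 4:
        profiles.extend(challenge_profiles(master.randrange(2**31)))
    while len(profiles) < n:
        profiles.append(_random_profile(master.randrange(2**31),
                                        checklist, lexicon))
    return [
        generate_patient(profile, checklist, lexicon, rules,
                         patient_id=f"P{i + 1:04d}")
        for i, profile in enumerate(profiles[:n])
    ]


def write_cohort(bundles: Sequence[GroundTruthBundle], out_dir) -> None:
    """Write bundles to disk in the standard formats, one directory each.

    Each patient directory holds the bundle manifest (+ JSONL documents
    and CSV labs), the lexicon CSV, gold annotations JSONL, and an
    expectations file with the per-criterion statuses.
    """
    import json
    import os

    from .emr import write_bundle
    from .metrics import write_gold_jsonl
    from .tagger import write_lexicon_csv

    os.makedirs(out_dir, exist_ok=True)
    for bundle in bundles:
        pdir = os.path.join(out_dir, bundle.record.patient_id)
        os.makedirs(pdir, exist_ok=True)
        write_bundle(bundle.record, os.path.join(pdir, "bundle.json"))
        write_lexicon_csv(bundle.lexicon, os.path.join(pdir, "lexicon.csv"))
        write_gold_jsonl(bundle.gold, os.path.join(pdir, "gold.jsonl"))
        with open(os.path.join(pdir, "expected.json"), "w",
                  encoding="utf-8") as fh:
            json.dump({
                "trial_name": bundle.checklist.trial_name,
                "checklist_version": bundle.checklist.version,
                "expected_statuses": [
                    {"criterion_label": item.label, "status": status.value}
                    for item, status in zip(bundle.checklist.items,
                                            bundle.expected_verdicts)
                ],
            }, fh, indent=2)
            fh.write("\n")
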