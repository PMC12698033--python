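# Methods

This note documents the screening model, the choices made where the
design was genuinely open, and what the synthetic-data results do and do
not establish.

## Rule model

A checklist is an ordered list of (criterion label, role, expression)
items; the label carries the criterion's verbatim prose and the role is
INCLUSION or EXCLUSION. Expressions are finite trees: AND/OR nodes with
≥ 2 children, NOT with exactly one, and two leaf kinds.

**Lab leaf** — lab item, comparator (<, ≤, >, ≥, =), finite threshold,
optional unit, and a mode: ABSOLUTE compares the measured value,
RATIO_TO_CONTROL compares value ÷ control value (threshold must be
positive). **Concept leaf** — one or more concept references (CUI +
preferred name) with a non-empty set of document-type labels. Multiple
concepts inside one leaf are disjunctive: they model one clinical notion
with several codings (headache *or* its synonyms). A conjunction of
distinct notions ("diabetes with prior stroke") must use an explicit AND
node. This disjunctive reading was a genuinely open choice; the
alternative (conjunctive) is expressible with AND nodes, while the
converse would not be expressible at all.

**Temporal windows** are `amount × unit` (days/months/years) before or
after the index time, resolved to half-open intervals: BEFORE gives
`[index − amount, index)` — an event exactly `amount` before the index
is inside, an event at the index is outside — and AFTER gives
`[index, index + amount)`. Month/year steps are calendar arithmetic with
month-end clamping (one month before 31 March is 28/29 February), not
fixed 30/365-day spans; an independent `calendar.monthrange`-based
re-derivation in the test suite pins this behaviour.

Constructors do not validate; `validate_expr` returns every invariant
violation as data with the offending node path, so malformed rule trees
can be reported precisely rather than raising on first contact. Rule
files are versioned JSON; unknown schema versions and unknown fields are
rejected, not ignored — rule bases gate patient safety decisions and
silent field loss is the failure mode to avoid. The authoring DSL is
line-oriented text (one statement per item) with a canonical
pretty-printer; `parse(pretty_print(c)) = c` and
`deserialize(serialize(c)) = c` hold structurally and are enforced as
properties. Criterion identifiers are positional (`i3.c2`), assigned
identically by the parser and expected by the printer.

## Concept extraction

The tagger is a deterministic dictionary matcher. Tokenization uses
Unicode word characters with hyphenated terms kept as single tokens —
determinism was preferred over linguistic sophistication throughout.
Matching is greedy longest-match, left-to-right, non-overlapping, over
token sequences; forms are case-insensitive unless flagged
case-sensitive (short acronyms such as `MI`, `ICH`, `CVA`, where case
carries the signal). A surface form declared by two entries resolves to
the first-declared entry and logs a warning; word-sense disambiguation
is out of scope. Broad drug classes are modelled as one CUI with many
member-drug surface forms (the *Anticoagulant* entry enumerates
warfarin, apixaban, dabigatran, edoxaban, rivaroxaban) — class-level
screening criteria resolve without any ontology traversal.

**Negation** is trigger/scope based. A mention is negated iff a
pre-trigger phrase ends fewer than `scope_window` tokens before its
first token, or a post-trigger starts fewer than `scope_window` tokens
after its last token, with no terminator token in the gap. The default
`scope_window` is 6 tokens — wide enough for "no history of significant
head injury", narrow enough that a sentence-initial "no" does not reach
an unrelated clause — and the trigger/terminator lists ship as an
editable JSON data file. Context beyond negation (hypotheticals, family
history) is an extension point, not implemented.

The whole extractor sits behind `annotate_record(record, lexicon,
allowed_types, rules) → {doc_id: [annotations]}`; any engine honouring
that signature (e.g. a wrapper around an external UMLS mapper) can
replace it without touching inference or reporting.

## Inference

Three statuses per criterion: MET, NOT_MET, UNKNOWN. The three-valued
design is deliberate even though a reviewer-facing checklist shows
yes/no: a missing lab is epistemically different from a negative
finding, and coercing it to "no" silently is exactly the unsafe
behaviour a screening tool must not exhibit. Reports map UNKNOWN to
"no (needs review)".

* Lab leaf: take the most recent in-window result for the item
  (timestamp ties broken by input order, last wins — a corrected
  re-entry supersedes the original); UNKNOWN if none, or if ratio mode
  finds no control value; otherwise compare.
* Concept leaf: MET iff at least one non-negated mention of a wanted
  CUI lies in a document of a requested type whose timestamp is in
  window, citing every qualifying mention as evidence. If the requested
  document types exist but hold no qualifying affirmed mention, the
  leaf is NOT_MET (closed-world: that is how a human answers a
  checklist from records). UNKNOWN is reserved for the structural case
  — the record contains no document of the requested types at all.
* Combinators: strong Kleene. AND is MET iff all children MET, NOT_MET
  iff any child NOT_MET, else UNKNOWN; OR is the dual; NOT swaps
  MET/NOT_MET and fixes UNKNOWN. Equivalently min/max under
  NOT_MET < UNKNOWN < MET, which is how the independent test oracle
  computes it.

Conjunctions such as "diabetes with prior stroke" are evaluated with
each conjunct searched independently across the whole record: the two
mentions need not share a document. Whether same-document co-occurrence
should be required is a real modelling question for criteria that
express a linked clinical state; record-wide evaluation was chosen as
the weaker, recall-favouring reading, and is worth flagging to anyone
adapting the rules.

Exclusion criteria are *not* polarity-inverted by the engine. A verdict
answers the criterion as written; the report prints the role beside the
status and leaves the trial-level eligible/ineligible call to the human
reviewer, as does the screening workflow this models.

## Metrics

`concept_prf` scores predicted annotations against gold spans per CUI.
A predicted affirmed annotation matches a gold affirmed item iff CUIs
agree and spans overlap (default; exact-span is available). Matching is
one-to-one via maximum bipartite matching, so one long prediction cannot
absorb two gold mentions; the test suite checks equivalence against an
exhaustive enumeration matcher. Negated predictions are not detections,
and negated gold items are not detection targets — they are audit
records of correctly-absent findings. Zero-denominator precision or
recall is reported as "n/a" rather than 0 or 1; inventing a convention
would make aggregate tables lie.

Checklist accuracy is the mean of per-criterion correctness indicators
(max 1). NASA-TLX takes six 0–20 subscale ratings and six
pairwise-comparison weights summing to 15, returning
`(Σ wᵢrᵢ / 15) × 5` on 0–100; omitting the weights computes the
unweighted "raw TLX" variant, offered because weight elicitation is
often unavailable. SUS follows the standard scoring: odd items
contribute `r − 1`, even items `5 − r`, sum × 2.5.

## Synthetic EMR generator

The generator emulates the screening setting: per patient, a stream of
admission/outpatient/discharge/nursing/radiology notes assembled from
neutral boilerplate, with criterion-relevant mentions planted
affirmatively ("History of warfarin documented.") or under negation
("No history of head injury per the patient."), distractor mentions of
the same surface forms, and lab series including ratio-to-control
items. Hard facts can be buried in outpatient notes, the least
prominent stream. Defaults: 8 documents per patient with a
0.30/0.30/0.20/0.20 admission/outpatient/discharge/nursing mix,
distractor density ≈ 1 mention per filler note, index time fixed at a
reference date-time, filler notes spread over the preceding ~4 years —
sizes chosen to look like a compact multi-department record while
keeping every mention auditable by eye.

Three construction rules make the ground truth exact rather than
approximate. One planted fact per document, so a negation trigger can
never scope onto a neighbouring planted mention. Template prose is
checked at generation time to contain no lexicon surface form and no
trigger or terminator token. Distractors are only placed at (document
type, timestamp) positions where every criterion referencing that CUI
is blocked by the type filter or the window — so they exercise the
filters without perturbing any verdict. Expected verdicts are computed
during generation from the planted facts, lab series, and document
inventory by a separate evaluator inside the generator; the inference
engine being tested plays no part in producing its own expectations.

The bundled study fixture is an eleven-item thrombolysis-style
checklist (platelets, glucose, APTT ratio-to-control within 7 days,
windowed history criteria over 3 weeks / 14 days / 48 hours / 3 months
/ 3 years, an unwindowed hemorrhage history, and a cross-document
diabetes-with-prior-stroke conjunction) over a ten-concept synthetic
lexicon. Cohorts lead with four challenge patients: the buried
anticoagulant, an APTT of 42 s against a 30 s control (ratio exactly
1.4, MET under ≤, with a disqualifying older value just outside the
window), the cross-document conjunction, and a record containing only
negated mentions and no labs.

**What passing does and does not show.** Perfect planted-truth recovery
and perfect extraction P/R/F1 on generated cohorts demonstrate that the
pipeline's mechanics — matching, negation scoping, type and window
filtering, ratio arithmetic, three-valued combination, evidence
plumbing — are internally exact. They say nothing about performance on
real clinical prose, whose misspellings, ad-hoc abbreviations,
nonstandard negation ("pt w/o hx of..."), copy-forward noise, and
multilingual fragments the generator deliberately does not model. On
real text a lexicon tagger's recall is bounded by lexicon coverage and
its precision by sense ambiguity; the validation workflow (`trialscreen
validate` against expert gold annotations) exists precisely because
every new criterion should be checked against annotated records before
deployment.

## Numerical and degenerate-input choices

* Ratio comparisons use ordinary floating-point division and exact
  comparator semantics with no epsilon — thresholds are policy values,
  not measurements. The boundary case 42/30 ≤ 1.4 holds because both
  sides round to the same double.
* Timestamps are ISO-8601, timezone-naive within a record; a date-only
  timestamp means midnight. Lab timestamp ties: last input row wins.
* Document selection orders by (timestamp, doc_id) for stable output.
* An empty record annotates to an empty mapping; a concept criterion
  over it is UNKNOWN (no documents of the requested types).
* DSL numbers accept scientific notation; the pretty-printer emits
  integers without a decimal point and uses `repr` otherwise, so
  print/parse round-trips preserve value bit-for-bit.
* Cohort per-patient seeds are drawn from a master `random.Random`
  seeded by the caller; every stochastic choice flows from that seed
  and regeneration is byte-identical.

## Known limitations

* Lexicon lookup is exact token-sequence matching: no stemming, no
  spelling tolerance, no nested/overlapping mention output.
* Negation is scope-window based; long-range or morphological negation
  ("afebrile") requires lexicon- or trigger-level workarounds.
* Concept criteria are existential; criteria about counts, trends, or
  value changes over time ("two readings above…") are out of scope.
* The engine evaluates conjuncts record-wide (see above); criteria
  requiring same-document or same-encounter co-occurrence need a
  dedicated leaf type.
* English text only.
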