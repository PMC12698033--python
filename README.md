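# trialscreen

Eligibility screening for clinical trials over electronic medical
records (EMRs): a machine-readable rule language for trial checklists, a
deterministic lexicon-based clinical concept tagger with negation
detection, and a three-valued inference engine that answers each
criterion from a patient's lab results and timestamped clinical notes,
with every answer linked to its evidence.

## The problem

Screening a patient against a trial protocol means answering a checklist
of inclusion and exclusion criteria — "Platelets < 100,000", "APTT ≤ 1.4
× control within 7 days", "headache or head injury within three years",
"diabetes with prior stroke" — from a record that mixes structured lab
tables with years of free-text notes across departments. Doing this by
hand under time pressure (acute stroke, for instance) is slow and
error-prone, and the critical contraindication is often buried in an
outpatient note nobody opens. This package automates the mechanical
part: compile the checklist once into rule expressions, extract concept
mentions from every document up front, then answer each criterion with
an auditable verdict and pointers into the record.

## How it works

**Rules.** A checklist item is a tree of criteria joined by AND / OR /
NOT. Leaves are either lab criteria — a comparator against a threshold,
in absolute units or as a ratio to a control value — or concept
criteria: a family of concept unique identifiers (CUIs) searched in
selected document types. Any leaf can carry a temporal window measured
from the patient's index time (e.g. triage). Windows are half-open
`[index − amount, index)`; month and year windows use calendar
arithmetic with month-end clamping. Checklists are authored in a small
text DSL or as versioned JSON rule files.

**Extraction.** A dictionary tagger scans each document with greedy
longest-match, token-boundary-aware lookup of surface forms (synonyms,
acronyms, enumerated member drugs of broad classes like
*Anticoagulant*), assigns each mention its CUI and semantic type, and
flags negated mentions using trigger/scope rules ("no history of …",
"denies …", with terminators like "but" ending the scope). The extractor
sits behind a plain `annotate_record` contract so an external concept
mapping engine can be swapped in.

**Inference.** Each criterion is answered MET, NOT_MET, or UNKNOWN.
Missing data is never silently coerced to "no": an absent in-window lab,
a ratio criterion without a control value, or a record with none of the
requested document types all yield UNKNOWN, which reports render as
"no (needs review)". Combinators follow strong-Kleene three-valued
logic. Verdicts answer criteria *as written*; exclusion polarity is
displayed, not inverted.

**Validation.** Extraction quality is scored per CUI against
gold-standard spans (precision / recall / F1, any-overlap or exact-span
matching, one-to-one). The study outcome scores are implemented too:
checklist accuracy (mean per-criterion correctness, max 1), the weighted
NASA-TLX workload score (0–100), and the SUS usability score (0–100).

**Synthetic EMR.** Because no real patient data ships with the package,
a deterministic generator produces full bundles — multi-department note
streams with affirmatively and negatively planted mentions, distractor
mentions that no criterion can qualify, and lab series including
ratio-to-control items — together with gold annotations and expected
verdicts computed at generation time, independently of the engine.

## Worked example

```python
from trialscreen import annotate_record, screen_patient
from trialscreen.synth import generate_cohort

bundle = generate_cohort(4, base_seed=7)[0]   # buried-contraindication case
annotations = annotate_record(bundle.record, bundle.lexicon)
result = screen_patient(bundle.checklist, bundle.record, annotations)
for v in result.verdicts:
    print(f"{v.status.value:8s} [{v.role.value.lower():9s}] {v.criterion_label}")
print("relevant documents:", sorted(result.relevant_docs))
```

```
MET      [inclusion] APTT no more than 1.4 times the control value within 7 days
NOT_MET  [exclusion] Platelet count below 100,000 per uL
NOT_MET  [exclusion] Blood glucose below 50 mg/dL
NOT_MET  [exclusion] Head injury or prior stroke within 3 months
NOT_MET  [exclusion] Headache or head injury within 3 years
NOT_MET  [exclusion] History of intracranial hemorrhage
NOT_MET  [exclusion] Internal bleeding within 3 weeks
NOT_MET  [exclusion] Major surgery within 14 days
MET      [exclusion] Anticoagulant use within 48 hours
NOT_MET  [exclusion] Seizure at presentation
NOT_MET  [exclusion] Diabetes mellitus with prior stroke
relevant documents: ['P0001-d001']
```

The patient passes the APTT inclusion criterion but trips the
anticoagulant exclusion: a warfarin mention documented only in an
outpatient note one day before index. `relevant_docs` is exactly the
set a reviewer should open first, and the rendered report (Markdown or
self-contained HTML) highlights the mention in place, with negated
mentions styled separately.

The same pipeline is available from a shell:

```sh
trialscreen simulate --n 4 --seed 7 --out-dir cohort/
trialscreen compile rules.dsl rules.json
trialscreen screen --rules rules.json --bundle cohort/P0001/bundle.json \
    --lexicon cohort/P0001/lexicon.csv --out-dir report/
trialscreen validate --bundle cohort/P0001/bundle.json \
    --lexicon cohort/P0001/lexicon.csv --gold cohort/P0001/gold.jsonl \
    --out prf.csv
```

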