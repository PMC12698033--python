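from __future__ import annotations

from datetime import datetime

import pytest

from trialscreen.emr import ClinicalDocument, LabResult, PatientRecord
from trialscreen.rules import LabItem
from trialscreen.synth import default_checklist, default_lexicon
from trialscreen.tagger import default_negation_rules

INDEX = datetime(2024, 6, 15, 9, 30)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def checklist(lexicon):
    return default_checklist(lexicon)


@pytest.fixture(scope="session")
def negation_rules():
    return default_negation_rules()


def make_doc(doc_id="d1", doc_type="admission note", timestamp=INDEX,
             text="Nothing to report."):
    return ClinicalDocument(doc_id=doc_id, doc_type=doc_type,
                            timestamp=timestamp, text=text)


def make_lab(code="PLT", value=150_000.0, control=None, timestamp=INDEX,
             name="", unit=""):
    return LabResult(item=LabItem(code=code, name=name), value=value,
                     unit=unit, control_value=control, timestamp=timestamp)


def make_record(documents=(), labs=(), patient_id="P1", index_time=INDEX):
    return PatientRecord(patient_id=patient_id, index_time=index_time,
                         documents=tuple(documents), labs=tuple(labs))
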