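# Thrombolysis-style eligibility checklist used as the package's study
# fixture.  Eleven items mixing lab thresholds (absolute and
# ratio-to-control), windowed concept lookups, and a cross-concept
# conjunction.

checklist "rt-PA-style thrombolysis screen" version "1.0"

include "APTT no more than 1.4 times the control value within 7 days": lab "APTT" <= 1.4 x control within 7 days before index
exclude "Platelet count below 100,000 per uL": lab "PLT" < 100000
exclude "Blood glucose below 50 mg/dL": lab "GLU" < 50 unit "mg/dL"
exclude "Head injury or prior stroke within 3 months": (concept "Head injury" in [admission note, outpatient note, discharge summary] within 3 months before index) or (concept "Prior stroke" in [admission note, outpatient note, discharge summary] within 3 months before index)
exclude "Headache or head injury within 3 years": (concept "Headache" in [outpatient note, admission note] within 3 years before index) or (concept "Head injury" in [outpatient note, admission note] within 3 years before index)
exclude "History of intracranial hemorrhage": concept "Intracranial hemorrhage" in [admission note, outpatient note, discharge summary, radiology report]
exclude "Internal bleeding within 3 weeks": concept "Internal bleeding" in [admission note, outpatient note, discharge summary] within 21 days before index
exclude "Major surgery within 14 days": concept "Major surgery" in [admission note, outpatient note, discharge summary] within 14 days before index
exclude "Anticoagulant use within 48 hours": concept "Anticoagulant" in [admission note, outpatient note] within 2 days before index
exclude "Seizure at presentation": concept "Seizure" in [admission note] within 7 days before index
exclude "Diabetes mellitus with prior stroke": (concept "Diabetes mellitus" in [admission note, outpatient note, discharge summary]) and (concept "Prior stroke" in [admission note, outpatient note, discharge summary])
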