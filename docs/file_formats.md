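# Cohort file formats

Both formats carry the same data model (see `smartscreen.records`); saving
and re-loading a validated cohort is the identity in either format. Dates
are ISO-8601 (`YYYY-MM-DD`) everywhere.

## JSON (`--format json`)

One file, a top-level array with one object per person:

```json
[
 {
  "person_id": "4710-223",
  "name": "A. Example",
  "birth_date": "1964-02-11",
  "sex": "male",
  "marital_status": "married",
  "contact": {"email": "a@example.org", "phone": "+98-900-1234567"},
  "history": {
   "known_diseases": ["hypertension"],
   "cancer_history": [{"site": "skin", "year": 2008}],
   "family_history": [
    {"relation": "father", "condition": "diabetes"},
    {"relation": "mother", "condition": "breast_cancer", "onset_age": 45}
   ],
   "smoking": "current",
   "pack_years": 20.0,
   "medications": ["amlodipine"],
   "on_antihypertensives": true
  },
  "exams": [
   {"date": "2012-06-01", "systolic": 138, "diastolic": 86,
    "height": 171.0, "weight": 92.0, "waist": 106.0, "other_findings": []}
  ],
  "results": [
   {"test_code": "FPG", "date": "2012-06-01", "numeric_value": 104, "units": "mg/dL"},
   {"test_code": "LIPID_PROFILE", "date": "2012-06-01",
    "components": {"total_cholesterol": 228, "hdl": 37, "ldl": 148, "triglycerides": 195}},
   {"test_code": "PAP_SMEAR", "date": "2011-03-10", "text_report": "NILM"}
  ],
  "visits": [
   {"date": "2012-06-01", "tests_requested": ["FPG", "LIPID_PROFILE"]}
  ]
 }
]
```

Field notes:

* `person_id` — opaque unique string (e.g. a national identification
  code); no checksum is enforced.
* `sex` — `male` | `female`; `marital_status` — `single` | `married` |
  `divorced` | `widowed` | `unknown`; `smoking` — `never` | `former` |
  `current`.
* `test_code` — `FPG`, `LIPID_PROFILE`, `FOBT`,
  `SIGMOIDOSCOPY_COLONOSCOPY`, `PAP_SMEAR`, `MAMMOGRAPHY`, `PSA`,
  `SKIN_EXAM`.
* `relation` — `mother`, `father`, `sister`, `brother`, `daughter`, `son`
  (first-degree) or `grandmother`, `grandfather`, `aunt`, `uncle`,
  `cousin`.
* A result needs at least one of `numeric_value`, `components`,
  `text_report`. Contact fields are optional; a missing channel disables
  that reminder channel only.

Invariants checked at load time (violations are reported per field and
person, all at once): unique non-empty `person_id`; `birth_date` strictly
before every exam/result/visit date; `systolic > diastolic > 0`; positive
height/weight/waist; distinct visit dates; non-negative `pack_years`.

## CSV (`--format csv`)

A *directory* of four normalized files keyed by `person_id`:

| file | columns |
| --- | --- |
| `persons.csv` | `person_id,name,birth_date,sex,marital_status,email,phone,smoking,pack_years,on_antihypertensives,known_diseases,cancer_history,family_history,medications` |
| `exams.csv` | `person_id,date,systolic,diastolic,height,weight,waist,other_findings` |
| `results.csv` | `person_id,test_code,date,numeric_value,units,components,text_report` |
| `visits.csv` | `person_id,date,tests_requested` |

List- and object-valued cells (`known_diseases`, `cancer_history`,
`family_history`, `medications`, `other_findings`, `components`,
`tests_requested`) hold JSON-encoded values, e.g.
`"[""FPG"", ""LIPID_PROFILE""]"`. Every `person_id` in the three entity
files must appear in `persons.csv`.
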