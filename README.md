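# smartscreen

Guideline-driven decision support for preventive screening programmes, with
a built-in screening-quality audit.

Occupational and community health clinics that run periodic health
examinations face two recurring failures: people attend irregularly, and
the screening tests requested at each visit drift away from what the
guidelines actually indicate — indicated tests go unrequested (*underuse*)
while non-indicated tests are requested anyway (*overuse*). `smartscreen`
is a library and CLI for clinic teams and health-services researchers that

* evaluates a **declarative screening ruleset** (age windows, repeat
  intervals, risk-factor modifiers) against person records to produce a
  screening plan: indicated tests with due dates, referral specialties and
  health messages;
* runs the standard **clinical calculators** automatically — BMI and blood
  pressure severity categories, abdominal obesity, fasting-glucose and
  ATP-III lipid bands, metabolic syndrome (≥3 of 5 criteria), and the
  point-table Framingham 10-year hard-CHD risk score;
* schedules **reminder notifications** at the fixed offsets −14, −7, −3,
  +3, +7 and +14 days around each due date (e-mail and SMS as data
  channels; ICS export);
* **audits** a cohort's visit log against a ruleset. For each test a 2×2
  tally of indication × request yields

  underuse = `indicated, not requested / indicated`,
  overuse = `not indicated, requested / not indicated`,
  inappropriateness = `(underused + overused) / cases` (or `/ requested`),

  plus coverage (attended/eligible) and irregular attendance (any year
  without a visit, or any inter-visit gap > 365 days). Percentages are
  truncated — not rounded — to two decimals, in exact integer arithmetic.

A synthetic-cohort module generates realistic workplace cohorts (including
a deterministic 261-person benchmark whose audit reproduces the package's
reference tallies exactly), so everything is testable without real patient
data.

## Worked example

Evaluate the shipped default ruleset for one 48-year-old male smoker on
antihypertensive treatment (obese, waist 106 cm, BP 138/86, FPG 104 mg/dL,
lipids 228/37/148/195), as of 2012-06-15:

```python
from datetime import date
import smartscreen as ss

plan = ss.evaluate_rules(record, ss.default_ruleset(), date(2012, 6, 15))
```

The plan prints:

```
FOBT                       due 2012-06-15  overdue=True  -> gastroenterologist
FPG                        due 2015-06-01  overdue=False -> internist
LIPID_PROFILE              due 2017-05-31  overdue=False -> internist
condition: bmi_obese - BMI 31.5 kg/m2
condition: high_normal_blood_pressure - 138/86 mmHg
condition: abdominal_obesity - waist 106 cm
condition: impaired_fasting_glucose - FPG 104 mg/dL
condition: borderline_hyperlipidemia
condition: low_hdl - HDL 37 mg/dL
condition: metabolic_syndrome - 5 criteria: abdominal_obesity, elevated_bp,
           elevated_fpg, high_triglycerides, low_hdl
condition: chd_risk_high - 10-year CHD risk 30+%
referrals: cardiologist, gastroenterologist, internist
```

Reading this: colorectal screening (annual FOBT from age 45) has never been
done, so it is due immediately and overdue; glucose and lipids were just
tested, so their next rounds fall one interval (3 y and 5 y) later. The
calculators flag metabolic syndrome with all five criteria and a
Framingham point total in the top risk band, which adds the cardiologist
referral.

The same workflow from the shell:

```bash
smartscreen simulate --n 330 --seed 1 --out cohort.json
smartscreen screen --input cohort.json --as-of 2012-06-15 --out plans.json
smartscreen remind --input cohort.json --as-of 2012-06-15 \
    --window-start 2012-06-01 --window-end 2012-12-31 --ics reminders.ics
smartscreen audit --input cohort.json \
    --period-start 2009-01-01 --period-end 2011-12-31 --eligible 330
```

`audit` prints a per-test table of underuse/overuse/inappropriateness with
the requested-test counts and grand total.

## Layout

| Module | Contents |
| --- | --- |
| `smartscreen.records` | person/cohort data model, CSV/JSON I/O, validation-as-data |
| `smartscreen.calculators` | BMI, BP, glucose, lipids, metabolic syndrome, Framingham |
| `smartscreen.engine` | ruleset schema + loader, indication logic, screening plans |
| `smartscreen.reminders` | six-shot reminder schedule, pending events, ICS export |
| `smartscreen.quality` | 2×2 tallies, underuse/overuse/inappropriateness, coverage, audit |
| `smartscreen.synthetic` | random cohorts, exact tally-matched cohorts, benchmark fixture |
| `smartscreen.cli` | `smartscreen screen | audit | remind | simulate` |

File-format and ruleset schemas are documented in `docs/`; the modelling
choices and their rationale in `docs/methods.md`.
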