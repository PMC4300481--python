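# Ruleset schema

A ruleset is a YAML (or JSON) document; the shipped default lives at
`src/smartscreen/data/default_ruleset.yaml` and is meant to be copied and
edited. Load with `smartscreen.load_ruleset(path)` — every constraint
below is checked at load time and violations raise a config error naming
the rule index and field.

```yaml
version: "my-clinic-2026.1"        # free-form version string (required)

rules:                             # one entry per (test_code, target_sex)
  - test_code: FPG                 # one of the eight screening test codes
    target_sex: any                # male | female | any (default any)
    start_age: 45                  # completed years, inclusive
    stop_age: 76                   # optional, exclusive; omit for open-ended
    interval_days: 1095            # repeat interval, whole days, > 0
    referral_specialty: internist  # optional
    messages: [fpg_info]           # ids into message_catalog
    eligibility:                   # optional predicate; person is skipped
      none_of:                     #   entirely when it fails
        - {pred: known_disease, code: hysterectomy}
    modifiers:                     # optional risk-factor adjustments
      - description: free text shown in the rationale
        start_age: 25              # replaces start_age when lower
        interval_days: 365         # replaces interval when shorter
        when:                      # predicate that arms the modifier
          all_of:
            - {pred: bmi_ge, value: 25}
            - any_of:
                - {pred: smoker}
                - {pred: bp_ge, systolic: 135, diastolic: 80}
                - {pred: family_history, condition: diabetes, degree: first}
                - {pred: known_disease, code: hypertension}
      - description: onset-anchored start
        start_rule:                # alternative to a fixed start_age:
          condition: breast_cancer #   min(relative onset ages) - years_before,
          degree: first            #   never below floor; floor used when no
          years_before: 10         #   onset age is recorded
          floor: 30
        when: {pred: family_history, condition: breast_cancer, degree: first}

general_messages: [general_prevention]   # rendered for every plan

condition_referrals:               # detected condition -> specialty
  metabolic_syndrome: internist

message_catalog:                   # id -> template; placeholders limited to
  fpg_info: >-                     #   {name} {person_id} {test} {due_date}
    {name}, your {test} is due on {due_date}.   # {specialty}
```

## Predicates

Leaves (the closed vocabulary — unknown names are rejected):

| predicate | parameters | true when |
| --- | --- | --- |
| `bmi_ge` | `value` | latest exam BMI ≥ value |
| `bp_ge` | `systolic`, `diastolic` | latest exam systolic ≥ s **or** diastolic ≥ d |
| `smoker` | — | current smoker |
| `family_history` | `condition`, `degree` (`first`/`any`) | matching family-history entry |
| `known_disease` | `code` | code in known diseases |

Combinators: `all_of`, `any_of`, `none_of`, each taking a non-empty list
and nesting freely. A leaf that needs an exam (BMI, BP) is false when no
exam is on file.

## Validation rules

* at most one rule per `(test_code, target_sex)`, and a test may not mix
  an `any` rule with sex-specific ones;
* `interval_days > 0` (also in modifiers); `start_age < stop_age`;
* a modifier must change something (`start_age`, `start_rule` or
  `interval_days`);
* every message id (rules and `general_messages`) must resolve in
  `message_catalog`, and templates may only use the placeholders listed
  above.

Semantics reminder: all bounds are lower-inclusive / upper-exclusive, and
when several modifiers fire the earliest start age and shortest interval
win.
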