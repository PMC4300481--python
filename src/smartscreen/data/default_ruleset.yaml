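# Default screening ruleset shipped with smartscreen.
#
# These are editable circa-2012 defaults assembled from widely used adult
# preventive-care recommendations; they are a documented stand-in, not a
# reproduction of any single guideline document. The engine is data-driven:
# substitute your own file with the same schema (see docs/ruleset_schema.md).
#
# Ages are in completed years; age windows are [start_age, stop_age) —
# lower bound inclusive, upper bound exclusive. Intervals are whole days.
version: "2012-defaults.1"

rules:
  - test_code: FPG
    target_sex: any
    start_age: 45
    interval_days: 1095          # every 3 years
    referral_specialty: internist
    messages: [fpg_info]
    modifiers:
      - description: overweight plus an additional diabetes risk factor
        start_age: 25
        when:
          all_of:
            - {pred: bmi_ge, value: 25}
            - any_of:
                - {pred: smoker}
                - {pred: bp_ge, systolic: 135, diastolic: 80}
                - {pred: family_history, condition: diabetes, degree: first}
                - {pred: known_disease, code: hypertension}
                - {pred: known_disease, code: dyslipidemia}
      - description: sustained blood pressure at or above 135/80
        start_age: 25
        when: {pred: bp_ge, systolic: 135, diastolic: 80}

  - test_code: LIPID_PROFILE
    target_sex: male
    start_age: 35
    interval_days: 1825          # every 5 years
    referral_specialty: internist
    messages: [lipid_info]
    modifiers: &lipid_modifiers
      - description: coronary heart disease risk factors
        start_age: 20
        when:
          any_of:
            - {pred: smoker}
            - {pred: known_disease, code: hypertension}
            - {pred: known_disease, code: diabetes}
            - {pred: family_history, condition: premature_chd, degree: first}

  - test_code: LIPID_PROFILE
    target_sex: female
    start_age: 45
    interval_days: 1825
    referral_specialty: internist
    messages: [lipid_info]
    modifiers: *lipid_modifiers

  - test_code: FOBT
    target_sex: any
    start_age: 45
    stop_age: 76                 # through age 75
    interval_days: 365           # annual
    referral_specialty: gastroenterologist
    messages: [crc_info]
    modifiers:
      - description: first-degree family history of colorectal cancer
        start_age: 40
        when: {pred: family_history, condition: colorectal_cancer, degree: first}

  - test_code: SIGMOIDOSCOPY_COLONOSCOPY
    target_sex: any
    start_age: 50
    stop_age: 76
    interval_days: 1825          # flexible sigmoidoscopy every 5 years
    referral_specialty: gastroenterologist
    messages: [crc_info]
    modifiers:
      - description: first-degree family history of colorectal cancer
        start_age: 40
        when: {pred: family_history, condition: colorectal_cancer, degree: first}

  - test_code: PAP_SMEAR
    target_sex: female
    start_age: 21
    stop_age: 66                 # through age 65
    interval_days: 1095
    referral_specialty: gynecologist
    messages: [pap_info]
    eligibility:
      none_of:
        - {pred: known_disease, code: hysterectomy}

  - test_code: MAMMOGRAPHY
    target_sex: female
    start_age: 40
    interval_days: 730           # every 1-2 years
    referral_specialty: oncologist
    messages: [mammo_info]
    modifiers:
      - description: first-degree family history of breast cancer; start ten
          years before the relative's age at onset, not earlier than 30
        start_rule:
          condition: breast_cancer
          degree: first
          years_before: 10
          floor: 30
        when: {pred: family_history, condition: breast_cancer, degree: first}

  - test_code: PSA
    target_sex: male
    start_age: 50
    interval_days: 365
    referral_specialty: urologist
    messages: [psa_info, psa_shared_decision]
    modifiers:
      - description: first-degree family history of prostate cancer
        start_age: 45
        when: {pred: family_history, condition: prostate_cancer, degree: first}

  - test_code: SKIN_EXAM
    target_sex: any
    start_age: 18
    interval_days: 365
    referral_specialty: dermatologist
    messages: [skin_info]
    eligibility:
      any_of:
        - {pred: family_history, condition: skin_cancer, degree: any}
        - {pred: known_disease, code: atypical_nevi}
        - {pred: known_disease, code: immunosuppression}

general_messages: [general_prevention, general_lifestyle]

condition_referrals:
  metabolic_syndrome: internist
  impaired_fasting_glucose: internist
  diabetic_range_glucose: endocrinologist
  hypertension_stage1: internist
  hypertension_stage2: cardiologist
  chd_risk_high: cardiologist

message_catalog:
  general_prevention: >-
    Dear {name}, regular periodic health examination helps detect risk
    factors and disease early, when they are most treatable.
  general_lifestyle: >-
    A balanced diet, regular physical activity and not smoking reduce your
    risk of chronic disease.
  fpg_info: >-
    A fasting plasma glucose test ({test}) is recommended for you; it is due
    on {due_date}.
  lipid_info: >-
    A fasting lipid profile ({test}) is recommended for you; it is due on
    {due_date}.
  crc_info: >-
    Colorectal cancer screening ({test}) is recommended for you; it is due
    on {due_date}.
  pap_info: >-
    Cervical cytology ({test}) is recommended for you; it is due on
    {due_date}.
  mammo_info: >-
    Breast cancer screening ({test}) is recommended for you; it is due on
    {due_date}.
  psa_info: >-
    Prostate cancer screening ({test}) is recommended for you; it is due on
    {due_date}.
  psa_shared_decision: >-
    Prostate-specific antigen screening has benefits and harms; please
    discuss this test with your physician before deciding (shared decision).
  skin_info: >-
    A periodic skin examination ({test}) is recommended for you given your
    risk factors; it is due on {due_date}.
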