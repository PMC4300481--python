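# Clinical cut points and point tables used by smartscreen.calculators.
# Versioned so guideline updates touch data, not code. Band convention
# everywhere: lower bound inclusive, upper bound exclusive.
version: "2012.1"

bmi:
  # kg/m2 upper bounds of the first three classes
  underweight_below: 18.5
  normal_below: 25.0
  overweight_below: 30.0

blood_pressure:
  # mmHg lower bounds per class, applied to each component; the person's
  # label is the worse of the two component labels.
  systolic: {high_normal: 120, stage1: 140, stage2: 160}
  diastolic: {high_normal: 80, stage1: 90, stage2: 100}

fasting_glucose:
  # mg/dL
  impaired_from: 100
  diabetic_from: 126

lipids:
  # mg/dL; [borderline_from, high_from] per analyte
  total_cholesterol: {borderline_from: 200, high_from: 240}
  ldl: {borderline_from: 130, high_from: 160}
  triglycerides: {borderline_from: 150, high_from: 200}
  low_hdl_below: {male: 40, female: 50}

abdominal_obesity:
  # waist circumference, cm; obesity when strictly greater
  waist_above: {male: 102, female: 88}

metabolic_syndrome:
  waist_above: {male: 102, female: 88}
  triglycerides_from: 150
  hdl_below: {male: 40, female: 50}
  bp_from: {systolic: 130, diastolic: 85}
  fpg_from: 100
  criteria_required: 3

framingham:
  # Point-table estimator of 10-year hard coronary heart disease risk
  # (sex-specific age, age-banded total-cholesterol and smoking points,
  # HDL points, treated/untreated systolic points; total points looked up
  # in a sex-specific risk table).
  risk_category: {intermediate_from: 10, high_from: 20}
  age_bands: [20, 35, 40, 45, 50, 55, 60, 65, 70, 75]   # lower bounds, last band 75-79
  chol_age_bands: [20, 40, 50, 60, 70]                   # lower bounds for chol/smoking points
  chol_bands: [0, 160, 200, 240, 280]                    # mg/dL lower bounds
  male:
    age_points: [-9, -4, 0, 3, 6, 8, 10, 11, 12, 13]
    # rows: cholesterol band; columns: chol_age_bands
    chol_points:
      - [0, 0, 0, 0, 0]
      - [4, 3, 2, 1, 0]
      - [7, 5, 3, 1, 0]
      - [9, 6, 4, 2, 1]
      - [11, 8, 5, 3, 1]
    smoker_points: [8, 5, 3, 1, 1]
    hdl_points: {ge60: -1, from50: 0, from40: 1, below40: 2}
    sbp_points:  # lower bounds 0,120,130,140,160
      untreated: [0, 0, 1, 1, 2]
      treated: [0, 1, 2, 2, 3]
    risk_table:  # total points -> 10-year risk percent; below first entry -> "<1"
      0: 1
      1: 1
      2: 1
      3: 1
      4: 1
      5: 2
      6: 2
      7: 3
      8: 4
      9: 5
      10: 6
      11: 8
      12: 10
      13: 12
      14: 16
      15: 20
      16: 25
      17: 30   # 17 or more: ">=30"
  female:
    age_points: [-7, -3, 0, 3, 6, 8, 10, 12, 14, 16]
    chol_points:
      - [0, 0, 0, 0, 0]
      - [4, 3, 2, 1, 1]
      - [8, 6, 4, 2, 1]
      - [11, 8, 5, 3, 2]
      - [13, 10, 7, 4, 2]
    smoker_points: [9, 7, 4, 2, 1]
    hdl_points: {ge60: -1, from50: 0, from40: 1, below40: 2}
    sbp_points:
      untreated: [0, 1, 2, 3, 4]
      treated: [0, 3, 4, 5, 6]
    risk_table:
      9: 1
      10: 1
      11: 1
      12: 1
      13: 2
      14: 2
      15: 3
      16: 4
      17: 5
      18: 6
      19: 8
      20: 11
      21: 14
      22: 17
      23: 22
      24: 27
      25: 30   # 25 or more: ">=30"
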