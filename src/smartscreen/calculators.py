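"""Deterministic clinical classifiers and risk scores.

Everything in this module is a pure function of its inputs plus the cut
points in ``data/thresholds.yaml``; the band convention throughout is lower
bound inclusive, upper bound exclusive (BMI 25.0 is overweight, FPG 100
mg/dL is impaired). Categorizers are total on their valid domain: their
bands partition it, so every input lands in exactly one class.

The coronary-risk estimator is the point-table formulation of the
Framingham 10-year hard-CHD score: sex-specific integer points for age
band, age-banded total cholesterol and smoking, HDL, and treated/untreated
systolic pressure are summed and looked up in a sex-specific risk table.
The tables live in the thresholds file so they are auditable cell by cell
and replaceable without touching code.
"""

from __future__ import annotations

from bisect import bisect_right
from enum import Enum
from importlib import resources
from typing import Optional

import yaml
from pydantic import BaseModel

from .records import PhysicalExam, Sex


def _load_thresholds() -> dict:
    with resources.files("smartscreen.data").joinpath("thresholds.yaml").open() as fh:
        return yaml.safe_load(fh)


THRESHOLDS: dict = _load_thresholds()


class BMICategory(str, Enum):
    underweight = "underweight"
    normal = "normal"
    overweight = "overweight"
    obese = "obese"


class BMIResult(BaseModel):
    value: float  # kg/m2
    category: BMICategory


class BPLabel(str, Enum):
    normal = "normal"
    high_normal = "high_normal"
    stage1 = "stage1"
    stage2 = "stage2"


_BP_ORDER = [BPLabel.normal, BPLabel.high_normal, BPLabel.stage1, BPLabel.stage2]


class BPCategory(BaseModel):
    label: BPLabel
    systolic: float
    diastolic: float


class LipidPanel(BaseModel):
    total_cholesterol: float
    hdl: float
    ldl: float
    triglycerides: float


class LipidBand(str, Enum):
    desirable = "desirable"
    borderline = "borderline"
    high = "high"


class LipidCategories(BaseModel):
    total_cholesterol: LipidBand
    ldl: LipidBand
    triglycerides: LipidBand
    low_hdl: bool


class GlycemicCategory(str, Enum):
    normal = "normal"
    impaired_fasting_glucose = "impaired_fasting_glucose"
    diabetic_range = "diabetic_range"


class GlycemicResult(BaseModel):
    fpg: float  # mg/dL
    category: GlycemicCategory


class MetSynCriterion(str, Enum):
    abdominal_obesity = "abdominal_obesity"
    high_triglycerides = "high_triglycerides"
    low_hdl = "low_hdl"
    elevated_bp = "elevated_bp"
    elevated_fpg = "elevated_fpg"


class MetabolicSyndromeResult(BaseModel):
    criteria_met: list[MetSynCriterion]
    positive: bool
    missing_components: list[str] = []


class RiskCategory(str, Enum):
    low = "low"            # <10 %
    intermediate = "intermediate"  # 10-20 %
    high = "high"          # >20 %


class FraminghamResult(BaseModel):
    points: int
    ten_year_risk: float   # percent; 1.0 with label "<1" for the floor band
    risk_label: str        # "<1", "5", "30+", ...
    category: RiskCategory


def compute_bmi(weight: float, height: float) -> BMIResult:
    """Body-mass index from weight in kg and height in cm."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    value = weight / (height / 100.0) ** 2
    t = THRESHOLDS["bmi"]
    if value < t["underweight_below"]:
        cat = BMICategory.underweight
    elif value < t["normal_below"]:
        cat = BMICategory.normal
    elif value < t["overweight_below"]:
        cat = BMICategory.overweight
    else:
        cat = BMICategory.obese
    return BMIResult(value=value, category=cat)


def _component_bp_label(value: float, bounds: dict) -> BPLabel:
    if value >= bounds["stage2"]:
        return BPLabel.stage2
    if value >= bounds["stage1"]:
        return BPLabel.stage1
    if value >= bounds["high_normal"]:
        return BPLabel.high_normal
    return BPLabel.normal


def categorize_bp(systolic: float, diastolic: float) -> BPCategory:
    """Severity label for an office blood pressure; the worse component wins."""
    if not (systolic > diastolic > 0):
        raise ValueError("require systolic > diastolic > 0")
    t = THRESHOLDS["blood_pressure"]
    label = max(_component_bp_label(systolic, t["systolic"]),
                _component_bp_label(diastolic, t["diastolic"]),
                key=_BP_ORDER.index)
    return BPCategory(label=label, systolic=systolic, diastolic=diastolic)


def detect_abdominal_obesity(waist: float, sex: Sex) -> bool:
    """Waist circumference strictly above the sex-specific cut (cm)."""
    if waist <= 0:
        raise ValueError("waist must be positive")
    return waist > THRESHOLDS["abdominal_obesity"]["waist_above"][Sex(sex).value]


def categorize_fpg(fpg: float) -> GlycemicResult:
    if fpg <= 0:
        raise ValueError("fpg must be positive")
    t = THRESHOLDS["fasting_glucose"]
    if fpg < t["impaired_from"]:
        cat = GlycemicCategory.normal
    elif fpg < t["diabetic_from"]:
        cat = GlycemicCategory.impaired_fasting_glucose
    else:
        cat = GlycemicCategory.diabetic_range
    return GlycemicResult(fpg=fpg, category=cat)


def _three_band(value: float, borderline_from: float, high_from: float) -> LipidBand:
    if value < borderline_from:
        return LipidBand.desirable
    if value < high_from:
        return LipidBand.borderline
    return LipidBand.high


def categorize_lipids(panel: LipidPanel, sex: Sex) -> LipidCategories:
    """Per-analyte bands for a fasting lipid profile (mg/dL)."""
    t = THRESHOLDS["lipids"]
    return LipidCategories(
        total_cholesterol=_three_band(panel.total_cholesterol,
                                      t["total_cholesterol"]["borderline_from"],
                                      t["total_cholesterol"]["high_from"]),
        ldl=_three_band(panel.ldl, t["ldl"]["borderline_from"], t["ldl"]["high_from"]),
        triglycerides=_three_band(panel.triglycerides,
                                  t["triglycerides"]["borderline_from"],
                                  t["triglycerides"]["high_from"]),
        low_hdl=panel.hdl < t["low_hdl_below"][Sex(sex).value],
    )


def detect_metabolic_syndrome(
    exam: Optional[PhysicalExam],
    panel: Optional[LipidPanel],
    fpg: Optional[float],
    sex: Sex,
    treated_bp: bool = False,
) -> MetabolicSyndromeResult:
    """Metabolic syndrome: positive when at least three of the five
    criteria — abdominal obesity, elevated triglycerides, low HDL, elevated
    blood pressure (or treatment for it), elevated fasting glucose — are met.

    A missing input component counts as not met and is listed in
    ``missing_components``.
    """
    t = THRESHOLDS["metabolic_syndrome"]
    sex = Sex(sex)
    met: list[MetSynCriterion] = []
    missing: list[str] = []

    if exam is None:
        missing += ["waist", "blood_pressure"]
    else:
        if exam.waist > t["waist_above"][sex.value]:
            met.append(MetSynCriterion.abdominal_obesity)
        if (exam.systolic >= t["bp_from"]["systolic"]
                or exam.diastolic >= t["bp_from"]["diastolic"] or treated_bp):
            met.append(MetSynCriterion.elevated_bp)
    if exam is None and treated_bp:
        met.append(MetSynCriterion.elevated_bp)

    if panel is None:
        missing += ["triglycerides", "hdl"]
    else:
        if panel.triglycerides >= t["triglycerides_from"]:
            met.append(MetSynCriterion.high_triglycerides)
        if panel.hdl < t["hdl_below"][sex.value]:
            met.append(MetSynCriterion.low_hdl)
    if fpg is None:
        missing.append("fpg")
    elif fpg >= t["fpg_from"]:
        met.append(MetSynCriterion.elevated_fpg)

    met = sorted(set(met), key=lambda c: c.value)
    return MetabolicSyndromeResult(
        criteria_met=met,
        positive=len(met) >= t["criteria_required"],
        missing_components=missing,
    )


def _band_index(value: float, lower_bounds: list[float]) -> int:
    return max(bisect_right(lower_bounds, value) - 1, 0)


def framingham_risk(
    age: int,
    sex: Sex,
    total_cholesterol: float,
    hdl: float,
    systolic: float,
    treated_bp: bool,
    smoker: bool,
) -> FraminghamResult:
    """10-year hard coronary heart disease risk via the sex-specific point tables.

    Valid for ages 20-79. The lowest tabulated band is "<1 %" (returned with
    ``ten_year_risk`` 1.0 and ``risk_label`` ``"<1"``); the top band is open
    (label ``"30+"``).
    """
    f = THRESHOLDS["framingham"]
    sex = Sex(sex)
    if not (20 <= age <= 79):
        raise ValueError("framingham_risk is tabulated for ages 20-79")
    if total_cholesterol <= 0 or hdl <= 0 or systolic <= 0:
        raise ValueError("inputs must be positive")
    tab = f[sex.value]

    points = tab["age_points"][_band_index(age, f["age_bands"])]
    ci = _band_index(age, f["chol_age_bands"])
    points += tab["chol_points"][_band_index(total_cholesterol, f["chol_bands"])][ci]
    if smoker:
        points += tab["smoker_points"][ci]
    hp = tab["hdl_points"]
    if hdl >= 60:
        points += hp["ge60"]
    elif hdl >= 50:
        points += hp["from50"]
    elif hdl >= 40:
        points += hp["from40"]
    else:
        points += hp["below40"]
    sbp_bounds = [0, 120, 130, 140, 160]
    key = "treated" if treated_bp else "untreated"
    points += tab["sbp_points"][key][_band_index(systolic, sbp_bounds)]

    risk_table = {int(k): v for k, v in tab["risk_table"].items()}
    lo, hi = min(risk_table), max(risk_table)
    if points < lo:
        risk, label = 1.0, "<1"
    elif points >= hi:
        risk, label = float(risk_table[hi]), f"{risk_table[hi]}+"
    else:
        risk = float(risk_table[points])
        label = f"{risk_table[points]:g}"

    t = f["risk_category"]
    if risk < t["intermediate_from"]:
        cat = RiskCategory.low
    elif risk <= t["high_from"]:
        cat = RiskCategory.intermediate
    else:
        cat = RiskCategory.high
    return FraminghamResult(points=points, ten_year_risk=risk, risk_label=label, category=cat)


def mgdl_to_mmoll(value: float, analyte: str = "glucose") -> float:
    """Unit helper: mg/dL to mmol/L for glucose, cholesterol or triglycerides."""
    factors = {"glucose": 18.016, "cholesterol": 38.67, "triglycerides": 88.57}
    return value / factors[analyte]


def mmoll_to_mgdl(value: float, analyte: str = "glucose") -> float:
    factors = {"glucose": 18.016, "cholesterol": 38.67, "triglycerides": 88.57}
    return value * factors[analyte]
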