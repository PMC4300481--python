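"""Clinical classifiers: band lookups, boundary convention (lower bound
inclusive), partition/monotonicity properties, and hand-summed point-table
oracles for the coronary-risk score."""

from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smartscreen import calculators as calc
from smartscreen.records import PhysicalExam, Sex


class TestBMI:
    def test_hand_arithmetic(self):
        r = calc.compute_bmi(70, 175)
        assert r.value == pytest.approx(22.857, abs=1e-3)
        assert r.category == calc.BMICategory.normal

    def test_unit_identity_at_one_metre(self):
        assert calc.compute_bmi(63.0, 100).value == pytest.approx(63.0)

    @pytest.mark.parametrize("bmi,expect", [
        (18.4, "underweight"), (18.5, "normal"), (24.99, "normal"),
        (25.0, "overweight"), (29.99, "overweight"), (30.0, "obese")])
    def test_boundaries_lower_inclusive(self, bmi, expect):
        weight = bmi * 1.0  # height 100 cm makes value == weight
        assert calc.compute_bmi(weight, 100).category.value == expect

    @given(w=st.floats(30, 200), h=st.floats(120, 210))
    @settings(max_examples=50, derandomize=True)
    def test_doubling_weight_doubles_value(self, w, h):
        assert calc.compute_bmi(2 * w, h).value == pytest.approx(
            2 * calc.compute_bmi(w, h).value)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            calc.compute_bmi(0, 170)


class TestBloodPressure:
    @pytest.mark.parametrize("sys,dia,label", [
        (118, 78, "normal"), (120, 78, "high_normal"), (118, 80, "high_normal"),
        (139, 89, "high_normal"), (140, 85, "stage1"), (118, 92, "stage1"),
        (160, 80, "stage2"), (150, 100, "stage2")])
    def test_bands_and_max_rule(self, sys, dia, label):
        assert calc.categorize_bp(sys, dia).label.value == label

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            calc.categorize_bp(80, 120)

    @given(sys=st.integers(81, 220), dia=st.integers(40, 80))
    @settings(max_examples=100, derandomize=True)
    def test_total_on_valid_domain(self, sys, dia):
        assert calc.categorize_bp(sys, dia).label in calc.BPLabel


class TestAbdominalObesityAndGlucose:
    @pytest.mark.parametrize("waist,sex,expect", [
        (103, Sex.male, True), (102, Sex.male, False),
        (88, Sex.female, False), (88.5, Sex.female, True),
        (60, Sex.male, False), (60, Sex.female, False)])
    def test_strict_waist_thresholds(self, waist, sex, expect):
        assert calc.detect_abdominal_obesity(waist, sex) is expect

    @pytest.mark.parametrize("fpg,cat", [
        (95, "normal"), (99.9, "normal"), (100, "impaired_fasting_glucose"),
        (125.9, "impaired_fasting_glucose"), (126, "diabetic_range")])
    def test_glucose_bands(self, fpg, cat):
        assert calc.categorize_fpg(fpg).category.value == cat

    @given(fpg=st.floats(40, 400))
    @settings(max_examples=100, derandomize=True)
    def test_glucose_bands_partition(self, fpg):
        assert calc.categorize_fpg(fpg).category in calc.GlycemicCategory


class TestLipids:
    def test_all_desirable(self):
        panel = calc.LipidPanel(total_cholesterol=180, ldl=100, triglycerides=120, hdl=55)
        r = calc.categorize_lipids(panel, Sex.male)
        assert (r.total_cholesterol, r.ldl, r.triglycerides) == (
            calc.LipidBand.desirable,) * 3
        assert not r.low_hdl

    def test_borderline_boundary(self):
        panel = calc.LipidPanel(total_cholesterol=200, ldl=100, triglycerides=120, hdl=55)
        assert calc.categorize_lipids(panel, Sex.male).total_cholesterol == calc.LipidBand.borderline

    @pytest.mark.parametrize("hdl,sex,low", [
        (39, Sex.male, True), (40, Sex.male, False),
        (49, Sex.female, True), (50, Sex.female, False)])
    def test_low_hdl_sex_specific(self, hdl, sex, low):
        panel = calc.LipidPanel(total_cholesterol=180, ldl=100, triglycerides=120, hdl=hdl)
        assert calc.categorize_lipids(panel, sex).low_hdl is low


def _exam(waist=80.0, sys=118, dia=70):
    return PhysicalExam(date=date(2011, 1, 1), systolic=sys, diastolic=dia,
                        height=170.0, weight=70.0, waist=waist)


class TestMetabolicSyndrome:
    def test_all_five_criteria(self):
        r = calc.detect_metabolic_syndrome(
            _exam(waist=110, sys=145, dia=92),
            calc.LipidPanel(total_cholesterol=240, ldl=160, triglycerides=200, hdl=30),
            fpg=110, sex=Sex.male)
        assert r.positive and len(r.criteria_met) == 5

    def test_two_criteria_negative(self):
        r = calc.detect_metabolic_syndrome(
            _exam(waist=110),
            calc.LipidPanel(total_cholesterol=180, ldl=100, triglycerides=160, hdl=55),
            fpg=90, sex=Sex.male)
        assert len(r.criteria_met) == 2 and not r.positive

    def test_exact_criterion_set(self):
        r = calc.detect_metabolic_syndrome(
            _exam(waist=103, sys=118, dia=70),
            calc.LipidPanel(total_cholesterol=190, ldl=110, triglycerides=150, hdl=39),
            fpg=90, sex=Sex.male, treated_bp=False)
        assert r.positive
        assert {c.value for c in r.criteria_met} == {
            "abdominal_obesity", "high_triglycerides", "low_hdl"}

    def test_treated_bp_counts_as_elevated(self):
        r = calc.detect_metabolic_syndrome(_exam(), None, None, Sex.male, treated_bp=True)
        assert calc.MetSynCriterion.elevated_bp in r.criteria_met

    def test_missing_components_count_as_not_met(self):
        r = calc.detect_metabolic_syndrome(None, None, None, Sex.female)
        assert not r.positive and not r.criteria_met
        assert set(r.missing_components) == {"waist", "blood_pressure",
                                             "triglycerides", "hdl", "fpg"}

    def test_monotone_in_added_criteria(self):
        base = calc.detect_metabolic_syndrome(
            _exam(waist=110, sys=145, dia=92),
            calc.LipidPanel(total_cholesterol=190, ldl=110, triglycerides=160, hdl=55),
            fpg=90, sex=Sex.male)
        more = calc.detect_metabolic_syndrome(
            _exam(waist=110, sys=145, dia=92),
            calc.LipidPanel(total_cholesterol=190, ldl=110, triglycerides=160, hdl=35),
            fpg=110, sex=Sex.male)
        assert set(c.value for c in base.criteria_met) <= set(c.value for c in more.criteria_met)
        assert not (base.positive and not more.positive)


class TestFramingham:
    # Hand-summed point oracles over the encoded tables
    @pytest.mark.parametrize("kw,points,risk,cat", [
        (dict(age=55, sex=Sex.male, total_cholesterol=250, hdl=39, systolic=146,
              treated_bp=False, smoker=True), 18, 30.0, "high"),
        (dict(age=45, sex=Sex.male, total_cholesterol=210, hdl=52, systolic=125,
              treated_bp=False, smoker=False), 8, 4.0, "low"),
        (dict(age=62, sex=Sex.female, total_cholesterol=185, hdl=48, systolic=138,
              treated_bp=True, smoker=False), 16, 4.0, "low"),
        (dict(age=38, sex=Sex.female, total_cholesterol=265, hdl=62, systolic=118,
              treated_bp=False, smoker=True), 16, 4.0, "low"),
        (dict(age=51, sex=Sex.female, total_cholesterol=205, hdl=38, systolic=162,
              treated_bp=False, smoker=True), 20, 11.0, "intermediate"),
    ])
    def test_hand_summed_profiles(self, kw, points, risk, cat):
        r = calc.framingham_risk(**kw)
        assert r.points == points
        assert r.ten_year_risk == risk
        assert r.category.value == cat

    def test_floor_band(self):
        r = calc.framingham_risk(age=23, sex=Sex.male, total_cholesterol=150, hdl=61,
                                 systolic=110, treated_bp=False, smoker=False)
        assert r.points == -10 and r.risk_label == "<1" and r.ten_year_risk <= 1.0

    def test_smoking_never_lowers_risk(self):
        for sex in Sex:
            for age in (25, 42, 58, 71):
                base = dict(age=age, sex=sex, total_cholesterol=210, hdl=45,
                            systolic=135, treated_bp=False)
                assert (calc.framingham_risk(smoker=True, **base).ten_year_risk
                        >= calc.framingham_risk(smoker=False, **base).ten_year_risk)

    def test_monotone_in_age_and_pressure(self):
        kw = dict(sex=Sex.female, total_cholesterol=190, hdl=50, treated_bp=False,
                  smoker=False)
        risks = [calc.framingham_risk(age=a, systolic=115, **kw).ten_year_risk
                 for a in (25, 37, 46, 57, 66, 77)]
        assert risks == sorted(risks)
        by_sbp = [calc.framingham_risk(age=55, systolic=s, **kw).ten_year_risk
                  for s in (110, 125, 135, 150, 170)]
        assert by_sbp == sorted(by_sbp)

    def test_age_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            calc.framingham_risk(age=19, sex=Sex.male, total_cholesterol=200,
                                 hdl=50, systolic=120, treated_bp=False, smoker=False)
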