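"""Rule engine: ruleset validation, indication logic, due dates, plans."""

from datetime import date

import pytest
import yaml

from smartscreen import engine
from smartscreen.errors import ConfigError
from smartscreen.records import (FamilyHistoryItem, MedicalHistory, PhysicalExam,
                                 Relation, Sex, TestCode, TestResult)

AS_OF = date(2012, 6, 15)


def _birth_for_age(age, on=AS_OF):
    return date(on.year - age, on.month, on.day)


class TestRulesetLoading:
    def test_default_ruleset_covers_all_audited_tests(self, ruleset):
        assert len(ruleset.rules) >= 7
        covered = {r.test_code for r in ruleset.rules}
        assert {TestCode.FPG, TestCode.LIPID_PROFILE, TestCode.FOBT,
                TestCode.SIGMOIDOSCOPY_COLONOSCOPY, TestCode.PAP_SMEAR,
                TestCode.MAMMOGRAPHY, TestCode.PSA} <= covered

    def _write(self, tmp_path, obj):
        p = tmp_path / "rs.yaml"
        p.write_text(yaml.safe_dump(obj))
        return p

    def test_zero_interval_rejected(self, tmp_path):
        obj = {"version": "t", "rules": [
            {"test_code": "FPG", "start_age": 45, "interval_days": 0}]}
        with pytest.raises(ConfigError, match="interval_days"):
            engine.load_ruleset(self._write(tmp_path, obj))

    def test_duplicate_rule_per_test_and_sex_rejected(self, tmp_path):
        rule = {"test_code": "PSA", "target_sex": "male",
                "start_age": 50, "interval_days": 365}
        obj = {"version": "t", "rules": [rule, dict(rule)]}
        with pytest.raises(ConfigError, match="duplicate"):
            engine.load_ruleset(self._write(tmp_path, obj))

    def test_unknown_predicate_rejected(self, tmp_path):
        obj = {"version": "t", "rules": [
            {"test_code": "FPG", "start_age": 45, "interval_days": 365,
             "modifiers": [{"start_age": 30, "when": {"pred": "horoscope"}}]}]}
        with pytest.raises(ConfigError, match="horoscope"):
            engine.load_ruleset(self._write(tmp_path, obj))

    def test_unknown_message_id_rejected(self, tmp_path):
        obj = {"version": "t", "rules": [
            {"test_code": "FPG", "start_age": 45, "interval_days": 365,
             "messages": ["missing_template"]}]}
        with pytest.raises(ConfigError, match="missing_template"):
            engine.load_ruleset(self._write(tmp_path, obj))

    def test_unknown_placeholder_rejected(self, tmp_path):
        obj = {"version": "t",
               "rules": [{"test_code": "FPG", "start_age": 45, "interval_days": 365}],
               "message_catalog": {"m": "hello {nonexistent_field}"}}
        with pytest.raises(ConfigError, match="nonexistent_field"):
            engine.load_ruleset(self._write(tmp_path, obj))


class TestIsIndicated:
    def test_sex_mismatch(self, ruleset, make_person):
        male = make_person(sex=Sex.male)
        rule = ruleset.rule_for(TestCode.PAP_SMEAR, Sex.female)
        indicated, rationale = engine.is_indicated(male, rule, AS_OF)
        assert not indicated and any("sex" in r for r in rationale)

    def test_start_age_inclusive(self, ruleset, make_person):
        rule = ruleset.rule_for(TestCode.FPG, Sex.male)
        at_start = make_person(birth=_birth_for_age(rule.start_age))
        below = make_person(birth=_birth_for_age(rule.start_age - 1))
        assert engine.is_indicated(at_start, rule, AS_OF)[0]
        assert not engine.is_indicated(below, rule, AS_OF)[0]

    def test_stop_age_exclusive(self, ruleset, make_person):
        rule = ruleset.rule_for(TestCode.FOBT, Sex.male)
        at_stop = make_person(birth=_birth_for_age(rule.stop_age))
        assert not engine.is_indicated(at_stop, rule, AS_OF)[0]

    def test_colorectal_family_history_modifier(self, ruleset, make_person):
        fh = MedicalHistory(family_history=[FamilyHistoryItem(
            relation=Relation.father, condition="colorectal_cancer", onset_age=55)])
        rec = make_person(birth=_birth_for_age(40), history=fh)
        rule = ruleset.rule_for(TestCode.FOBT, Sex.male)
        indicated, rationale = engine.is_indicated(rec, rule, AS_OF)
        assert indicated
        assert any("modifier fired" in r for r in rationale)
        plain = make_person(birth=_birth_for_age(40))
        assert not engine.is_indicated(plain, rule, AS_OF)[0]

    def test_pap_hysterectomy_exclusion(self, ruleset, make_person):
        rule = ruleset.rule_for(TestCode.PAP_SMEAR, Sex.female)
        woman = make_person(sex=Sex.female, birth=_birth_for_age(35))
        excluded = make_person(
            sex=Sex.female, birth=_birth_for_age(35),
            history=MedicalHistory(known_diseases=["hysterectomy"]))
        assert engine.is_indicated(woman, rule, AS_OF)[0]
        assert not engine.is_indicated(excluded, rule, AS_OF)[0]

    def test_mammography_onset_offset_start(self, ruleset, make_person):
        fh = MedicalHistory(family_history=[FamilyHistoryItem(
            relation=Relation.mother, condition="breast_cancer", onset_age=42)])
        rule = ruleset.rule_for(TestCode.MAMMOGRAPHY, Sex.female)
        # start = max(42 - 10, 30) = 32
        assert engine.is_indicated(
            make_person(sex=Sex.female, birth=_birth_for_age(32), history=fh),
            rule, AS_OF)[0]
        assert not engine.is_indicated(
            make_person(sex=Sex.female, birth=_birth_for_age(31), history=fh),
            rule, AS_OF)[0]


class TestNextDueDate:
    @pytest.mark.parametrize("last,interval,as_of,due,overdue", [
        (None, 365, date(2012, 6, 15), date(2012, 6, 15), True),
        (date(2011, 6, 1), 365, date(2012, 6, 15), date(2012, 5, 31), True),
        (date(2012, 6, 1), 365, date(2012, 6, 15), date(2013, 6, 1), False)])
    def test_calendar_arithmetic(self, last, interval, as_of, due, overdue):
        assert engine.next_due_date(last, interval, as_of) == (due, overdue)

    def test_positive_interval_required(self):
        with pytest.raises(ValueError):
            engine.next_due_date(None, 0, AS_OF)


class TestEvaluateRules:
    def test_young_low_risk_male_has_nothing_indicated(self, ruleset, make_person):
        plan = engine.evaluate_rules(make_person(birth=_birth_for_age(30)), ruleset, AS_OF)
        assert plan.indicated() == []
        assert plan.recommendations  # one per sex-applicable rule, all negative

    def test_sex_inapplicable_tests_absent(self, ruleset, make_person):
        male_plan = engine.evaluate_rules(make_person(sex=Sex.male), ruleset, AS_OF)
        female_plan = engine.evaluate_rules(
            make_person(sex=Sex.female, birth=date(1975, 3, 10)), ruleset, AS_OF)
        male_tests = {r.test_code for r in male_plan.recommendations}
        female_tests = {r.test_code for r in female_plan.recommendations}
        assert TestCode.PAP_SMEAR not in male_tests
        assert TestCode.MAMMOGRAPHY not in male_tests
        assert TestCode.PSA not in female_tests

    def test_indicated_iff_due_date(self, ruleset, make_person):
        plan = engine.evaluate_rules(make_person(birth=_birth_for_age(55)), ruleset, AS_OF)
        for rec in plan.recommendations:
            assert (rec.due_date is not None) == rec.indicated

    def test_never_tested_is_due_now_and_overdue(self, ruleset, make_person):
        plan = engine.evaluate_rules(make_person(birth=_birth_for_age(55)), ruleset, AS_OF)
        fpg = next(r for r in plan.recommendations if r.test_code == TestCode.FPG)
        assert fpg.indicated and fpg.due_date == AS_OF and fpg.overdue

    def test_recent_result_pushes_due_date(self, ruleset, make_person):
        rec = make_person(birth=_birth_for_age(55), results=[TestResult(
            test_code=TestCode.FPG, date=date(2012, 1, 10), numeric_value=92)])
        plan = engine.evaluate_rules(rec, ruleset, AS_OF)
        fpg = next(r for r in plan.recommendations if r.test_code == TestCode.FPG)
        assert fpg.due_date == date(2015, 1, 9) and not fpg.overdue

    def test_metabolic_syndrome_detected_with_referral(self, ruleset, make_person):
        exam = PhysicalExam(date=date(2012, 1, 5), systolic=136, diastolic=88,
                            height=170.0, weight=95.0, waist=108.0)
        rec = make_person(birth=_birth_for_age(50), exam=exam, results=[
            TestResult(test_code=TestCode.FPG, date=date(2012, 1, 5), numeric_value=108),
            TestResult(test_code=TestCode.LIPID_PROFILE, date=date(2012, 1, 5),
                       components={"total_cholesterol": 210, "hdl": 35,
                                   "ldl": 140, "triglycerides": 180})])
        plan = engine.evaluate_rules(rec, ruleset, AS_OF)
        names = {c.name for c in plan.detected_conditions}
        assert "metabolic_syndrome" in names
        assert ruleset.condition_referrals["metabolic_syndrome"] in plan.referrals

    def test_no_exam_marks_conditions_not_evaluable(self, ruleset, make_person):
        rec = make_person(exams=[])
        plan = engine.evaluate_rules(rec, ruleset, AS_OF)
        assert not plan.conditions_evaluable

    def test_deterministic(self, ruleset, make_person):
        rec = make_person(birth=_birth_for_age(48))
        assert (engine.evaluate_rules(rec, ruleset, AS_OF)
                == engine.evaluate_rules(rec, ruleset, AS_OF))

    def test_modifier_never_removes_indication_or_delays_due(self, ruleset, make_person):
        """Risk widening is monotone: adding a matching risk factor can only
        add indications and keep/advance the due date."""
        fh = MedicalHistory(family_history=[
            FamilyHistoryItem(relation=Relation.father, condition="colorectal_cancer"),
            FamilyHistoryItem(relation=Relation.father, condition="prostate_cancer"),
            FamilyHistoryItem(relation=Relation.mother, condition="diabetes")])
        for age in (25, 35, 42, 47, 55, 62):
            base = engine.evaluate_rules(
                make_person(birth=_birth_for_age(age)), ruleset, AS_OF)
            risky = engine.evaluate_rules(
                make_person(birth=_birth_for_age(age), history=fh), ruleset, AS_OF)
            for b, r in zip(base.recommendations, risky.recommendations):
                assert b.test_code == r.test_code
                if b.indicated:
                    assert r.indicated
                    assert r.due_date <= b.due_date


class TestMessages:
    def test_empty_plan_gets_general_messages_only(self, ruleset, make_person):
        plan = engine.evaluate_rules(make_person(birth=_birth_for_age(30)), ruleset, AS_OF)
        msgs = engine.render_messages(plan, ruleset.message_catalog, ruleset.general_messages)
        assert len(msgs) == len(ruleset.general_messages) > 0

    def test_each_indicated_test_yields_a_message(self, ruleset, make_person):
        plan = engine.evaluate_rules(make_person(birth=_birth_for_age(55)), ruleset, AS_OF)
        n_indicated = len(plan.indicated())
        assert n_indicated >= 3
        msgs = engine.render_messages(plan, ruleset.message_catalog, ruleset.general_messages)
        assert len(msgs) >= len(ruleset.general_messages) + n_indicated

    def test_missing_template_is_config_error(self, ruleset, make_person):
        plan = engine.evaluate_rules(make_person(birth=_birth_for_age(55)), ruleset, AS_OF)
        with pytest.raises(ConfigError):
            engine.render_messages(plan, {}, ruleset.general_messages)
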