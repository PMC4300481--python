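"""Guideline rule engine: from a person record to a screening plan.

A :class:`RuleSet` is declarative data — one :class:`ScreeningRule` per
screening test and target sex, each with an age window, a repeat interval,
optional risk-factor *modifiers* (which may lower the start age or shorten
the interval) and an optional eligibility predicate. Predicates come from a
closed, named vocabulary (``bmi_ge``, ``bp_ge``, ``smoker``,
``family_history``, ``known_disease``) combined with ``all_of`` / ``any_of``
/ ``none_of``; no executable code ever comes from configuration.

:func:`evaluate_rules` produces a :class:`ScreeningPlan`: one
:class:`Recommendation` per sex-applicable test (indicated or not, with the
due date for indicated ones), the clinically detected conditions from the
calculators, the deduplicated referral specialties, and rendered health
messages.

Tie-breaking is protective: when the base rule and one or more modifiers
all apply, the earliest start age and the shortest interval win. Ages are
completed years at the evaluation date; age windows are lower-inclusive,
upper-exclusive.
"""

from __future__ import annotations

import json
import string
from datetime import date, timedelta
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import calculators as calc
from .errors import ConfigError
from .records import (Contact, PersonRecord, Sex, SmokingStatus, TestCode,
                      FamilyHistoryItem)

# ---------------------------------------------------------------------------
# Predicates

_LEAF_SPECS: dict[str, set[str]] = {
    "bmi_ge": {"value"},
    "bp_ge": {"systolic", "diastolic"},
    "smoker": set(),
    "family_history": {"condition", "degree"},
    "known_disease": {"code"},
}
_COMBINATORS = ("all_of", "any_of", "none_of")


def validate_predicate(node, where: str) -> None:
    if not isinstance(node, dict):
        raise ConfigError(f"{where}: predicate must be a mapping, got {type(node).__name__}")
    combos = [k for k in node if k in _COMBINATORS]
    if combos:
        if len(node) != 1:
            raise ConfigError(f"{where}: combinator node must have exactly one key")
        children = node[combos[0]]
        if not isinstance(children, list) or not children:
            raise ConfigError(f"{where}: {combos[0]} needs a non-empty list")
        for i, child in enumerate(children):
            validate_predicate(child, f"{where}.{combos[0]}[{i}]")
        return
    name = node.get("pred")
    if name not in _LEAF_SPECS:
        raise ConfigError(f"{where}: unknown predicate {name!r} "
                          f"(known: {sorted(_LEAF_SPECS)})")
    allowed = _LEAF_SPECS[name] | {"pred"}
    extra = set(node) - allowed
    if extra:
        raise ConfigError(f"{where}: unexpected keys {sorted(extra)} for predicate {name!r}")
    if name == "family_history" and node.get("degree", "first") not in ("first", "any"):
        raise ConfigError(f"{where}: family_history degree must be 'first' or 'any'")


def _family_matches(fh: list[FamilyHistoryItem], condition: str, degree: str):
    return [item for item in fh
            if item.condition == condition and (degree == "any" or item.first_degree)]


def eval_predicate(node: dict, record: PersonRecord, as_of: date) -> bool:
    if "all_of" in node:
        return all(eval_predicate(c, record, as_of) for c in node["all_of"])
    if "any_of" in node:
        return any(eval_predicate(c, record, as_of) for c in node["any_of"])
    if "none_of" in node:
        return not any(eval_predicate(c, record, as_of) for c in node["none_of"])
    name = node["pred"]
    if name == "bmi_ge":
        exam = record.latest_exam(as_of)
        if exam is None:
            return False
        return calc.compute_bmi(exam.weight, exam.height).value >= node["value"]
    if name == "bp_ge":
        exam = record.latest_exam(as_of)
        if exam is None:
            return False
        return exam.systolic >= node["systolic"] or exam.diastolic >= node["diastolic"]
    if name == "smoker":
        return record.history.smoking == SmokingStatus.current
    if name == "family_history":
        return bool(_family_matches(record.history.family_history,
                                    node["condition"], node.get("degree", "first")))
    if name == "known_disease":
        return node["code"] in record.history.known_diseases
    raise ConfigError(f"unknown predicate {name!r}")  # pragma: no cover - validated


def describe_predicate(node: dict) -> str:
    for combo, joiner in (("all_of", " and "), ("any_of", " or "), ("none_of", " nor ")):
        if combo in node:
            inner = joiner.join(describe_predicate(c) for c in node[combo])
            prefix = "not: " if combo == "none_of" else ""
            return f"{prefix}({inner})"
    name = node["pred"]
    args = ", ".join(f"{k}={v}" for k, v in node.items() if k != "pred")
    return f"{name}({args})" if args else name


# ---------------------------------------------------------------------------
# Ruleset model

class OnsetOffsetRule(BaseModel):
    """Start-age rule derived from a relative's age at disease onset:
    start ``years_before`` years earlier, never below ``floor``. When the
    family-history entry records no onset age, the floor is used."""

    model_config = ConfigDict(extra="forbid")
    condition: str
    degree: Literal["first", "any"] = "first"
    years_before: int
    floor: int


class Modifier(BaseModel):
    model_config = ConfigDict(extra="forbid")
    description: str = ""
    when: dict
    start_age: Optional[int] = None
    start_rule: Optional[OnsetOffsetRule] = None
    interval_days: Optional[int] = None


class ScreeningRule(BaseModel):
    model_config = ConfigDict(extra="forbid")
    test_code: TestCode
    target_sex: Literal["male", "female", "any"] = "any"
    start_age: int
    stop_age: Optional[int] = None
    interval_days: int
    modifiers: list[Modifier] = Field(default_factory=list)
    eligibility: Optional[dict] = None
    referral_specialty: Optional[str] = None
    messages: list[str] = Field(default_factory=list)

    def applies_to_sex(self, sex: Sex) -> bool:
        return self.target_sex == "any" or self.target_sex == Sex(sex).value


class RuleSet(BaseModel):
    model_config = ConfigDict(extra="forbid")
    version: str
    rules: list[ScreeningRule]
    message_catalog: dict[str, str] = Field(default_factory=dict)
    general_messages: list[str] = Field(default_factory=list)
    condition_referrals: dict[str, str] = Field(default_factory=dict)

    def rule_for(self, test_code: TestCode, sex: Sex) -> Optional[ScreeningRule]:
        for rule in self.rules:
            if rule.test_code == test_code and rule.applies_to_sex(sex):
                return rule
        return None

    def rules_for_sex(self, sex: Sex) -> list[ScreeningRule]:
        out = [r for r in self.rules if r.applies_to_sex(sex)]
        return sorted(out, key=lambda r: r.test_code.value)

    def sex_applicable_tests(self, sex: Sex) -> list[TestCode]:
        return [r.test_code for r in self.rules_for_sex(sex)]


_TEMPLATE_FIELDS = {"name", "person_id", "test", "due_date", "specialty"}


def _validate_templates(catalog: dict[str, str]) -> None:
    fmt = string.Formatter()
    for mid, template in catalog.items():
        for _, field, _, _ in fmt.parse(template):
            if field is not None and field not in _TEMPLATE_FIELDS:
                raise ConfigError(
                    f"message {mid!r}: unknown placeholder {{{field}}} "
                    f"(allowed: {sorted(_TEMPLATE_FIELDS)})")


def _validate_ruleset(rs: RuleSet) -> RuleSet:
    seen: set[tuple[TestCode, str]] = set()
    scope: dict[TestCode, set[str]] = {}
    for i, rule in enumerate(rs.rules):
        where = f"rules[{i}] ({rule.test_code.value})"
        key = (rule.test_code, rule.target_sex)
        if key in seen:
            raise ConfigError(f"{where}: duplicate rule for "
                              f"({rule.test_code.value}, {rule.target_sex})")
        seen.add(key)
        scope.setdefault(rule.test_code, set()).add(rule.target_sex)
        if rule.interval_days <= 0:
            raise ConfigError(f"{where}: interval_days must be > 0")
        if rule.stop_age is not None and not rule.start_age < rule.stop_age:
            raise ConfigError(f"{where}: start_age must be < stop_age")
        if rule.eligibility is not None:
            validate_predicate(rule.eligibility, f"{where}.eligibility")
        for j, mod in enumerate(rule.modifiers):
            mw = f"{where}.modifiers[{j}]"
            validate_predicate(mod.when, f"{mw}.when")
            if mod.interval_days is not None and mod.interval_days <= 0:
                raise ConfigError(f"{mw}: interval_days must be > 0")
            if mod.start_age is None and mod.start_rule is None and mod.interval_days is None:
                raise ConfigError(f"{mw}: modifier changes nothing")
        for mid in rule.messages:
            if mid not in rs.message_catalog:
                raise ConfigError(f"{where}: unknown message id {mid!r}")
    for code, sexes in scope.items():
        if "any" in sexes and len(sexes) > 1:
            raise ConfigError(f"test {code.value}: cannot mix an 'any' rule "
                              f"with sex-specific rules")
    for mid in rs.general_messages:
        if mid not in rs.message_catalog:
            raise ConfigError(f"general_messages: unknown message id {mid!r}")
    _validate_templates(rs.message_catalog)
    return rs


def load_ruleset(path: str | Path) -> RuleSet:
    """Load and validate a ruleset from a YAML (or JSON) file."""
    path = Path(path)
    try:
        obj = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse ruleset {path}: {exc}") from exc
    try:
        rs = RuleSet.model_validate(obj)
    except Exception as exc:
        raise ConfigError(f"ruleset {path} violates the schema: {exc}") from exc
    return _validate_ruleset(rs)


def default_ruleset() -> RuleSet:
    """The editable default ruleset shipped with the package."""
    with resources.files("smartscreen.data").joinpath("default_ruleset.yaml").open() as fh:
        rs = RuleSet.model_validate(yaml.safe_load(fh))
    return _validate_ruleset(rs)


# ---------------------------------------------------------------------------
# Plan model

class Recommendation(BaseModel):
    test_code: TestCode
    indicated: bool
    rationale: list[str] = Field(default_factory=list)
    due_date: Optional[date] = None
    overdue: bool = False
    referral_specialty: Optional[str] = None
    messages: list[str] = Field(default_factory=list)


class DetectedCondition(BaseModel):
    name: str
    detail: str = ""


class ScreeningPlan(BaseModel):
    person_id: str
    as_of: date
    recommendations: list[Recommendation]
    detected_conditions: list[DetectedCondition]
    conditions_evaluable: bool
    referrals: list[str]
    contact: Contact = Field(default_factory=Contact)

    def indicated(self) -> list[Recommendation]:
        return [r for r in self.recommendations if r.indicated]


# ---------------------------------------------------------------------------
# Evaluation

def _modifier_start(mod: Modifier, record: PersonRecord) -> Optional[int]:
    if mod.start_rule is not None:
        sr = mod.start_rule
        matches = _family_matches(record.history.family_history, sr.condition, sr.degree)
        onsets = [m.onset_age for m in matches if m.onset_age is not None]
        if onsets:
            return max(min(onsets) - sr.years_before, sr.floor)
        return sr.floor
    return mod.start_age


def _effective(record: PersonRecord, rule: ScreeningRule, as_of: date):
    """Eligibility, protective effective start/interval, and rationale."""
    rationale: list[str] = []
    if not rule.applies_to_sex(record.sex):
        return False, rule.start_age, rule.interval_days, ["sex mismatch"]
    if rule.eligibility is not None and not eval_predicate(rule.eligibility, record, as_of):
        return False, rule.start_age, rule.interval_days, \
            [f"eligibility not met: {describe_predicate(rule.eligibility)}"]
    start, interval = rule.start_age, rule.interval_days
    for mod in rule.modifiers:
        if eval_predicate(mod.when, record, as_of):
            m_start = _modifier_start(mod, record)
            changed = []
            if m_start is not None and m_start < start:
                start = m_start
                changed.append(f"start_age -> {m_start}")
            if mod.interval_days is not None and mod.interval_days < interval:
                interval = mod.interval_days
                changed.append(f"interval -> {mod.interval_days} d")
            label = mod.description or describe_predicate(mod.when)
            rationale.append(f"modifier fired: {label}"
                             + (f" ({', '.join(changed)})" if changed else ""))
    return True, start, interval, rationale


def is_indicated(record: PersonRecord, rule: ScreeningRule, as_of: date):
    """Whether ``rule``'s test is indicated for ``record`` on ``as_of``.

    Returns ``(indicated, rationale)``; the rationale lists the fired
    modifiers and the age-window comparison that decided the outcome.
    """
    eligible, start, _, rationale = _effective(record, rule, as_of)
    if not eligible:
        return False, rationale
    age = record.age_on(as_of)
    stop = "inf" if rule.stop_age is None else rule.stop_age
    in_window = age >= start and (rule.stop_age is None or age < rule.stop_age)
    rationale.append(f"age {age} {'in' if in_window else 'outside'} [{start}, {stop})")
    return in_window, rationale


def next_due_date(last_result_date: Optional[date], interval_days: int, as_of: date):
    """Due date for the next round of a test and whether it is overdue.

    Never tested -> due immediately (and overdue); otherwise due one interval
    after the last result.
    """
    if interval_days <= 0:
        raise ValueError("interval_days must be > 0")
    if last_result_date is None:
        return as_of, True
    due = last_result_date + timedelta(days=interval_days)
    return due, due < as_of


def _latest_lipid_panel(record: PersonRecord, as_of: date) -> Optional[calc.LipidPanel]:
    res = record.latest_result(TestCode.LIPID_PROFILE, as_of)
    if res is None or not res.components:
        return None
    need = {"total_cholesterol", "hdl", "ldl", "triglycerides"}
    if not need <= set(res.components):
        return None
    return calc.LipidPanel(**{k: res.components[k] for k in need})


def detect_conditions(record: PersonRecord, as_of: date):
    """Run the clinical calculators on the most recent data.

    Returns ``(conditions, evaluable)``; with no physical exam on file the
    exam-based conditions cannot be evaluated and ``evaluable`` is False.
    """
    out: list[DetectedCondition] = []
    exam = record.latest_exam(as_of)
    panel = _latest_lipid_panel(record, as_of)
    fpg_res = record.latest_result(TestCode.FPG, as_of)
    fpg = fpg_res.numeric_value if fpg_res else None
    treated = record.history.on_antihypertensives
    evaluable = exam is not None

    if exam is not None:
        bmi = calc.compute_bmi(exam.weight, exam.height)
        if bmi.category in (calc.BMICategory.overweight, calc.BMICategory.obese):
            out.append(DetectedCondition(name=f"bmi_{bmi.category.value}",
                                         detail=f"BMI {bmi.value:.1f} kg/m2"))
        bp = calc.categorize_bp(exam.systolic, exam.diastolic)
        if bp.label != calc.BPLabel.normal:
            name = ("high_normal_blood_pressure" if bp.label == calc.BPLabel.high_normal
                    else f"hypertension_{bp.label.value}")
            out.append(DetectedCondition(name=name,
                                         detail=f"{exam.systolic:.0f}/{exam.diastolic:.0f} mmHg"))
        if calc.detect_abdominal_obesity(exam.waist, record.sex):
            out.append(DetectedCondition(name="abdominal_obesity",
                                         detail=f"waist {exam.waist:.0f} cm"))
    if fpg is not None:
        g = calc.categorize_fpg(fpg)
        if g.category == calc.GlycemicCategory.impaired_fasting_glucose:
            out.append(DetectedCondition(name="impaired_fasting_glucose",
                                         detail=f"FPG {fpg:.0f} mg/dL"))
        elif g.category == calc.GlycemicCategory.diabetic_range:
            out.append(DetectedCondition(name="diabetic_range_glucose",
                                         detail=f"FPG {fpg:.0f} mg/dL"))
    if panel is not None:
        bands = calc.categorize_lipids(panel, record.sex)
        worst = max((bands.total_cholesterol, bands.ldl, bands.triglycerides),
                    key=[calc.LipidBand.desirable, calc.LipidBand.borderline,
                         calc.LipidBand.high].index)
        if worst == calc.LipidBand.high:
            out.append(DetectedCondition(name="hyperlipidemia"))
        elif worst == calc.LipidBand.borderline:
            out.append(DetectedCondition(name="borderline_hyperlipidemia"))
        if bands.low_hdl:
            out.append(DetectedCondition(name="low_hdl", detail=f"HDL {panel.hdl:.0f} mg/dL"))
    if exam is not None or panel is not None or fpg is not None:
        ms = calc.detect_metabolic_syndrome(exam, panel, fpg, record.sex, treated)
        if ms.positive:
            out.append(DetectedCondition(
                name="metabolic_syndrome",
                detail=f"{len(ms.criteria_met)} criteria: "
                       + ", ".join(c.value for c in ms.criteria_met)))
    age = record.age_on(as_of)
    if exam is not None and panel is not None and 20 <= age <= 79:
        fr = calc.framingham_risk(age, record.sex, panel.total_cholesterol, panel.hdl,
                                  exam.systolic, treated,
                                  record.history.smoking == SmokingStatus.current)
        out.append(DetectedCondition(name=f"chd_risk_{fr.category.value}",
                                     detail=f"10-year CHD risk {fr.risk_label}%"))
    return out, evaluable


def _render(template_id: str, catalog: dict[str, str], context: dict) -> str:
    if template_id not in catalog:
        raise ConfigError(f"unknown message id {template_id!r}")
    try:
        return catalog[template_id].format(**context)
    except KeyError as exc:
        raise ConfigError(f"message {template_id!r}: unknown placeholder {exc}") from exc


def evaluate_rules(record: PersonRecord, ruleset: RuleSet, as_of: date) -> ScreeningPlan:
    """Build the screening plan for one person on one date.

    Deterministic: one recommendation per sex-applicable test, ordered by
    test code; sex-inapplicable tests are absent entirely.
    """
    recommendations: list[Recommendation] = []
    for rule in ruleset.rules_for_sex(record.sex):
        eligible, start, interval, rationale = _effective(record, rule, as_of)
        age = record.age_on(as_of)
        indicated = False
        due: Optional[date] = None
        overdue = False
        if eligible:
            stop = "inf" if rule.stop_age is None else rule.stop_age
            indicated = age >= start and (rule.stop_age is None or age < rule.stop_age)
            rationale = rationale + [f"age {age} {'in' if indicated else 'outside'} [{start}, {stop})"]
            if indicated:
                last = record.latest_result(rule.test_code, as_of)
                due, overdue = next_due_date(last.date if last else None, interval, as_of)
        context = {"name": record.name or record.person_id, "person_id": record.person_id,
                   "test": rule.test_code.value, "due_date": due.isoformat() if due else "",
                   "specialty": rule.referral_specialty or ""}
        messages = ([_render(mid, ruleset.message_catalog, context) for mid in rule.messages]
                    if indicated else [])
        recommendations.append(Recommendation(
            test_code=rule.test_code, indicated=indicated, rationale=rationale,
            due_date=due, overdue=overdue,
            referral_specialty=rule.referral_specialty if indicated else None,
            messages=messages))

    conditions, evaluable = detect_conditions(record, as_of)
    referrals = {r.referral_specialty for r in recommendations
                 if r.indicated and r.referral_specialty}
    for cond in conditions:
        if cond.name in ruleset.condition_referrals:
            referrals.add(ruleset.condition_referrals[cond.name])
    return ScreeningPlan(
        person_id=record.person_id, as_of=as_of, recommendations=recommendations,
        detected_conditions=conditions, conditions_evaluable=evaluable,
        referrals=sorted(referrals), contact=record.contact)


def render_messages(plan: ScreeningPlan, catalog: dict[str, str],
                    general_messages: list[str] | None = None) -> list[str]:
    """All messages for a plan: the general ones, then one block per
    indicated recommendation (already rendered by :func:`evaluate_rules`)."""
    _validate_templates(catalog)
    context = {"name": plan.person_id, "person_id": plan.person_id,
               "test": "", "due_date": "", "specialty": ""}
    out = [_render(mid, catalog, context) for mid in (general_messages or [])]
    for rec in plan.indicated():
        out.extend(rec.messages)
    return out


def screen_cohort(cohort: list[PersonRecord], ruleset: RuleSet,
                  on: date) -> list[PersonRecord]:
    """Software-assisted screening of a cohort: evaluate every person and
    append a visit on ``on`` requesting exactly the indicated tests.

    Returns new records (the input is not mutated); persons with no indicated
    test get no visit.
    """
    out = []
    for rec in cohort:
        plan = evaluate_rules(rec, ruleset, on)
        indicated = [r.test_code for r in plan.indicated()]
        new = rec.model_copy(deep=True)
        if indicated:
            from .records import VisitEvent
            new.visits = list(new.visits) + [VisitEvent(date=on, tests_requested=indicated)]
        out.append(new)
    return out


def plans_to_json(plans: list[ScreeningPlan]) -> str:
    return json.dumps([json.loads(p.model_dump_json(exclude_none=True)) for p in plans],
                      indent=1)
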