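# Methods

This note records what the package computes, the conventions it fixes
where practice varies, and what its synthetic data can and cannot show.

## The screening model

A screening programme is modelled as a **ruleset** applied to **person
records**. Each rule covers one test for one target sex and carries a
start age, an optional stop age, a repeat interval in whole days, optional
risk-factor *modifiers*, and an optional eligibility predicate. A test is
*indicated* for a person on a date when the sex matches, the eligibility
predicate (if any) holds, and the person's age in completed years lies in
`[start_age, stop_age)` — after modifiers have been applied. Modifiers
whose predicate matches may lower the start age (either to a fixed age or
to "n years before a first-degree relative's onset age, floored") or
shorten the interval; when several apply, the earliest start and shortest
interval win (the most protective interpretation). Everywhere in the
package, interval bounds are lower-inclusive and upper-exclusive: age
exactly `start_age` is inside the window, BMI 25.0 is overweight, FPG
100 mg/dL is impaired. One convention, stated once, tested everywhere.

Due dates are mechanical: a never-tested indicated test is due on the
evaluation date (and overdue); otherwise it is due one interval after the
most recent result, and overdue when that date has passed.

Predicates form a closed vocabulary (`bmi_ge`, `bp_ge`, `smoker`,
`family_history(condition, degree)`, `known_disease(code)`) combined with
`all_of` / `any_of` / `none_of`. Rulesets are pure data; nothing
executable is ever loaded from configuration.

### The default ruleset

The shipped defaults (`data/default_ruleset.yaml`) are editable circa-2012
adult preventive-care choices, not a reproduction of any single guideline
document: fasting glucose every 3 years from 45 (from 25 with BMI ≥ 25
plus a second risk factor, or sustained BP ≥ 135/80); lipid profile every
5 years, men from 35 and women from 45 (from 20 with CHD risk factors);
annual FOBT from 45 through 75 and sigmoidoscopy/colonoscopy every 5 years
from 50 through 75, both starting at 40 with a first-degree colorectal
family history; Pap smear for women 21–65 every 3 years, excluded after
hysterectomy; mammography from 40 every 2 years, or 10 years before a
first-degree relative's onset age (floor 30); PSA annually from 50 (45
with family history), always flagged for shared decision-making; periodic
skin examination at any adult age for people with skin-cancer risk
factors. Giving the two colorectal modalities different start ages is a
deliberate design choice of these defaults: it keeps stool-based and
endoscopic indication independently controllable, which both mirrors
programmes that stage the two modalities and is what lets the benchmark
tallies below be realized exactly.

## Clinical calculators

Thresholds live in one versioned data file (`data/thresholds.yaml`) so a
guideline revision edits data, not code. Blood pressure uses the
normal / high-normal / stage-1 / stage-2 bands with the worse component
deciding the label; lipids use the ATP-III 200/240 (total), 130/160 (LDL),
150/200 (TG) cuts with sex-specific low HDL (<40 men, <50 women);
metabolic syndrome is positive with ≥3 of waist >102/88 cm, TG ≥150,
low HDL, BP ≥130/85 (or treatment), FPG ≥100 — a missing component counts
as not met and is reported as missing, never as an error.

The coronary-risk estimator is the *point-table* formulation of the
Framingham 10-year hard-CHD score: sex-specific integer points for age
band, age-banded total-cholesterol and smoking points, HDL and
treated/untreated systolic pressure, summed and looked up in the
sex-specific risk table. The point version was chosen over the regression
coefficients because every cell is auditable against the table and
swappable by editing the data file. The lowest band is reported as risk
label "<1" (numeric value 1.0) and the open top band as "30+"; categories
are low <10 %, intermediate 10–20 %, high >20 %.

## Audit metrics

For an audit period, indication is judged **once, at the period end** (an
annual-examination audit; continuous re-evaluation would make the 2×2
tally ill-defined), and a test counts as requested when any visit inside
the period requested it. Underuse, overuse and inappropriateness follow
the definitions in the README. Two denominator conventions for
inappropriateness circulate — all sex-applicable persons ("cases") and all
requested tests — so both are implemented; `cases` is the default.
Percentages are truncated to two decimals in integer arithmetic
(`10000*num // den / 100`), because the reference tallies this package
reproduces were printed with truncation (108/261 → 41.37, 48/78 → 61.53);
conventional rounding is available as an option. A zero denominator
yields "not applicable" (`None`), never an exception.

Irregular attendance counts a participant as irregular when some calendar
year of the period has no visit or some inter-visit gap exceeds 365 days;
the denominator is all participants. Coverage is attendees over the
eligible population, reported truncated to an integer for the headline and
kept at two decimals internally.

## Reminders

Six events per due test per channel at offsets −14, −7, −3, +3, +7, +14
calendar days (no business-day adjustment, nothing on the due date
itself); the schedule is finite and stops after the +14-day event unless
the plan is re-evaluated. Post-due reminders cease once the test is
recorded as completed. Channels are gated by contact data: a missing
e-mail address or phone number silently disables that channel but never
affects the screening logic itself. The ICS writer emits date-valued
all-day VEVENTs and the paired reader exists for round-trip verification;
it is not a general iCalendar parser.

## Synthetic cohorts

`generate_cohort` emulates a mid-size workplace population. Defaults: 330
employees, 52 % women, ages truncated-normal on [23, 62] with realized
mean 36.4 and SD 8.68 years — the underlying location/scale are solved by
root finding so the *truncated* distribution has exactly those moments
(naively parameterizing the truncated normal with the targets would
realize mean ≈ 37.5 and SD ≈ 7.6). Risk-factor prevalences (smoking 12 %,
BMI ≥ 25 45 %, hypertension 12 %, dyslipidemia 15 %, diabetes 5 %,
hysterectomy 8 % of women, family histories 1–20 %) are modest
single-draw Bernoulli choices typical of a working-age cohort. The
manual-era visit log is generated by imperfect clinicians: each person
attends a given year with probability 0.27 (matching sparse manual-era
participation), an indicated test goes unrequested with probability 0.45
and a non-indicated one is requested with probability 0.25 — magnitudes
chosen to sit inside the wide range of request errors the audit layer is
designed to measure. Risk factors are drawn independently; the generator
does not model correlation structure between them, longitudinal disease
progression, or result values that feed back into attendance. Passing
tests on these cohorts therefore shows the *accounting* is right, not
that any particular real cohort looks like this.

`generate_tally_matched_cohort` is exact by construction: probe records —
one per sex × candidate age × risk-flag combination — are classified by
the rule engine itself, an integer program (HiGHS via
`scipy.optimize.milp`) chooses archetype multiplicities so the indicated
totals match the requested 2×2 marginals, and request events are dealt to
exactly the requested numbers of indicated and non-indicated persons.
Infeasible marginals fail loudly: consistency pre-checks name the
offending cells, and residual ILP infeasibility reports the indicated
totals it could not satisfy. The generated cohort is verified against the
marginals before being returned.

`benchmark_fixture` bundles the package's reference audit scenario: 261
staff (136 women, 125 men), a manual-era (2009–2011) visit log whose
per-test request counts are 157/155/1/0/30/22/1 (total 366) and whose 2×2
tallies match `BENCHMARK_MARGINALS` cell-for-cell, plus a software-era
(2012) log with 156/85/12/5/40/26/10 requests (total 334). Only the
marginals are constrained; every other attribute of the fixture (exact
ages, which persons carry which flags, visit dates) is arbitrary and
fixed by an internal seed. Three derived "inappropriateness over all
cases" figures for FOBT, sigmoidoscopy and mammography are deliberately
not part of the benchmark checks: the historically printed values for
those cells contradict the cell counts they were derived from, so the
package reports only quantities consistent with the tallies themselves.

## Problem sizes and numerical choices

The test suite and acceptance script use cohorts of 40–200 persons for
behavioural checks, 50 seeded 200-person cohorts for the
self-audit-zero property, 100 seeded 50-person cohorts for the
tally-conservation/recount equivalence, 1,000 random due dates for the
reminder schedule, and one 10,000-person cohort for demographic recovery
(3-standard-error bounds) — sizes at which every property is
comfortably resolved. All randomness flows through
`numpy.random.default_rng` seeds; fixed seeds make every generator, test
and CLI run bit-reproducible. Truncation of percentages is integer-exact;
the only floating-point truncation (`average_percent`) carries an epsilon
guard. Date arithmetic is whole-day `datetime.date` throughout; ages are
completed years.

## Known limitations

* Indication is a function of sex, age and recorded risk factors; result
  values (e.g. a positive FOBT) do not yet escalate follow-up testing.
* The default ruleset is a documented stand-in, not a transcription of any
  national guideline; programmes should ship their own file.
* The audit's period-end indication convention slightly misclassifies
  people who crossed an age boundary mid-period.
* Message templates are plain `str.format` strings with a fixed
  placeholder vocabulary; no localization layer.
* The tally-matched generator's archetype space is derived from the
  ruleset's age boundaries plus a fixed set of risk flags tied to the
  default predicate vocabulary; exotic custom rulesets may need new flags
  before arbitrary marginals become reachable.
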