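# Methods

This note records the models, conventions and design choices behind
`pedcds`, the assumptions they rest on, and what the synthetic fixtures do
and do not establish about behavior on real reference data.

## Percentile models

**BMI-for-age (LMS).** A growth reference is a per-(sex, age) triple
(L, M, S): Box-Cox power, median, coefficient of variation. A measurement
`x > 0` maps to

```
z = ((x/M)^L − 1) / (L·S)    if L ≠ 0
z = ln(x/M) / S              if L = 0
```

and the percentile is `100·Φ(z)`. The power branch is computed as
`expm1(L·ln(x/M)) / (L·S)`, which keeps the two branches consistent to
better than 1e-6 down to |L| ≈ 1e-8 (the branches agree analytically in the
limit). The transform is strictly increasing in `x` for fixed (L, M, S);
percentiles inherit strict monotonicity wherever Φ is resolvable in double
precision (|z| ≲ 8; beyond that the percentile saturates at 0 or 100, which
is a representation limit, not a model property).

**Row selection.** LMS rows are indexed at month midpoints (24.5, 25.5, …),
matching the published CDC file layout; a patient whose exact age in months
lies in `[t, t+1)` uses the row at `t + 0.5`. We deliberately snap rather
than interpolate across rows: lookup stays deterministic and the shipped
tables remain the single source of truth. Interpolation would change
percentiles by at most the between-row parameter drift over one month,
which is small against clinical decision thresholds but nonzero; callers
who need it can resample their reference to finer age steps.

**Age arithmetic.** Age is computed as completed calendar months plus the
elapsed fraction of the current anniversary-to-anniversary interval. When
the birth day-of-month exceeds the length of a month (born Jan 31, short
February), the anniversary rolls to that month's last day. This keeps age
strictly increasing day by day and makes every boundary test reproducible;
any other month-end convention would be equally defensible, but one must be
fixed.

**Blood pressure.** The BP reference is a knot table: per (sex, completed
age in years, height-percentile column), an ordered list of
(percentile, systolic, diastolic) knots, strictly increasing in all three
coordinates. An observed pressure is converted to a percentile by
piecewise-linear inversion between knots — exact at every knot — and values
outside the knot span are **censored** (`below_range` / `above_range`)
rather than extrapolated, because the table says nothing about tail shape.
Rules that need to react to extreme readings can condition on the censoring
flags or on absolute mmHg (the adolescent 120/80 floor does the latter).
The patient's height percentile is computed from a stature LMS reference
and snapped to the nearest height column, distance ties resolving toward
the 50th column; snapping (vs interpolating across columns) mirrors the
tables' granularity and is configurable at the call site by passing an
explicit `height_percentile`.

**Interpolation error bound.** On a normal reference with knots at
{5, 10, 25, 50, 75, 90, 95, 99}, linear inversion deviates from the exact
normal CDF by at most ~1.1 percentile points inside the 5th–95th span (the
acceptance script measures 1.097 on a 500-point grid); the widest gaps
(25↔50↔75) dominate. This bounds what knot-based tables can resolve and is
why the engine receives percentiles, not re-derived distribution
parameters.

## The knowledge layer

Guideline content is data. A rulebase document carries typed data elements
(numeric, enumerated, tri-state yes/no/unknown, date), recommendation and
supportive-action text keyed by token, numeric cutpoints (BMI percentile
thresholds; lipid bands), and rules: a risk domain, a half-open age band in
months, a trigger tree, a recommendation id, an evidence grade A–F, action
references. The parser resolves every cross-reference and rejects numeric
comparators on non-numeric variables; the schema contract is shipped as
`data/rulebase.schema.json` and enforced by equivalent in-code checks.

Conventions applied uniformly, each resolving a point guideline prose
leaves open:

* **Half-open age bands `[lower, upper)` in months.** Adjacent bands cannot
  overlap (the known failure mode at the infant-to-3 / 3-to-11 seam), and
  `validate_age_bands` reports any intersecting bands between same-trigger
  rules plus coverage gaps per (domain, recommendation) group. Overlaps are
  errors in strict mode; gaps are informational, since most recommendation
  families legitimately cover only part of the age range.
* **Inclusive toward the worse category.** A value exactly at a numeric
  boundary belongs to the more severe side, for triggers (`ge`/`le` on the
  severe side) and lipid bands alike; for HDL, where *low* is bad, the band
  at the bound falls downward. One convention makes the at-boundary
  expectation of every generated test case well defined.
* **Unknown never fires.** Every screener question carries an "unknown"
  option; firing clinical advice off missing data is unsafe. Triggers are
  evaluated in Kleene three-valued logic (unknown propagates through
  and/or), and only a definite *fire* emits a recommendation. Rules that
  should respond to missingness (e.g. obtain a family history, screen when
  lipids were never measured) use `is_unknown`, always conjoined with a
  definite clinical anchor so an empty session fires nothing.

The shipped rulebase is a representative encoding, not a transcription of
the full guideline corpus: 58 rules covering all eight domains, every
variable kind and every comparator, with the standard published cutpoints
(TC 170/200, LDL 110/130/160/190, non-HDL 120/145, HDL 40/45,
triglycerides 75/100 under age 10 and 90/130 from age 10, BMI percentiles
85/95/97, BP percentiles 90/95/99 and the adolescent 120/80 mmHg floor).
Recommendation copy is paraphrased and patient-specific.

## The engine

A `PatientSession` is the single current patient: demographics and
measurements, up to three BP readings (the screener's single pair counts as
one reading until the BP tool's readings supersede it), a lipid panel,
lifestyle and family-history answers. Variables are entered at most once
(`enter`), derived facts (age, BMI, percentiles, lipid categories, per-
condition tri-states) are recomputed from inputs on every access, and the
trashcan (`clear_session`) resets everything. "None of these" combined
with a named condition is rejected at entry rather than resolved silently —
the contradiction is the user's to fix.

`run_assessment` filters rules by tool context and age band (exact age in
months against the half-open band), evaluates triggers, deduplicates by
recommendation id (actions unioned in first-seen order, contributing rule
ids accumulated, first-seen grade kept — the shipped rulebase keeps grades
consistent within a recommendation), and orders output by the fixed domain
order (family history, nutrition and diet, physical activity, tobacco
exposure, lipids, overweight and obesity, then blood pressure and other
risk conditions), then rule id. Output JSON is byte-deterministic.

## Validation methodology

* **Boundary cases.** Every numeric boundary — trigger thresholds and both
  age-band edges (lower behaves like `ge`, upper like `lt`) — yields three
  probes at threshold−1, threshold, threshold+1 in the variable's native
  whole unit, with sibling conditions held at minimal satisfying values
  (numeric: the boundary value; enumerated: the first satisfying option;
  `any` branches other than the probed one left unknown). Cases are
  duplicated per tool context (BMI boundaries run in the screener, BMI and
  lipid tools), giving exactly 3 × 330 = 990 cases for the shipped
  rulebase. Expected outcomes come from comparator semantics alone; the
  recommendations implied by the satisfying context are frozen from the
  oracle so spurious extra firings are caught.
* **The brute-force oracle** re-evaluates raw trigger dictionaries with
  explicit Kleene truth tables, sharing no code with the engine. Engine
  and oracle agree on the fired set for 1,000 seeded random sessions (a
  per-variable sampler that hits exact thresholds with a point mass and
  leaves each answer missing with probability 0.35).
* **Scenarios.** 75 multi-domain sessions (5 handcrafted — all-unknown,
  obese adolescent smoker, dyslipidemia panel, stage-2 BP with obesity,
  family-history cluster — plus 70 seeded-random) with expected fired sets
  computed once by the oracle and frozen to `data/scenarios.json`;
  regeneration with the recorded seed reproduces the file exactly.
* **Mutation sensitivity.** Every single comparator swap (ge↔gt, le↔lt)
  and ±1 threshold shift on every numeric trigger atom (171 mutations) is
  caught by at least one frozen boundary case, the at-boundary probe by
  construction.

## Synthetic references: what they show and what they don't

No reference tables are downloaded at build or test time. The default
library is generated from smooth closed forms chosen to be realistically
shaped for ages 24–252 months: BMI median dipping in early childhood and
rising through adolescence (L = −2, S = 0.10), stature median saturating
with age (S = 0.04), and BP means rising linearly with age and gently with
height percentile (σ = 10/8 mmHg systolic/diastolic), with BP knots placed
at exact normal quantiles so inversion has an analytic truth to be checked
against. Passing tests therefore establish the *machinery* — parsing,
lookup conventions, the LMS transform, knot inversion, rule evaluation —
not the clinical values of any published table; with real CDC/NHLBI CSVs in
the documented dialects, results are exactly as good as those tables. The
synthetic cohort generator likewise spans the rulebase's trigger space
rather than any population's joint risk-factor distribution, so firing
*rates* in random sessions are not epidemiologically meaningful.

## Numerical and degenerate-input choices

Reference CSVs are UTF-8, comma-delimited, header row, decimal points only;
floats are written with `repr` and parsed with round-trip precision, so
write→read is bit-identical. Zero or more than three BP readings, systolic
≤ diastolic, non-positive measurements, HDL above total cholesterol,
unordered cutpoints and empty age bands are all rejected with typed errors;
ages outside reference coverage raise coverage errors naming the bounds
(the CLI maps input, coverage and parse errors to exit codes 2, 3, 1).
Derived non-HDL never overwrites an explicitly entered value and the
derivation is idempotent. Problem sizes in the test suite and acceptance
script (1,000 sessions, 10,000 monotonicity draws, 500 band sets, 990
cases, 171 mutations) run end to end in a few seconds on one CPU.
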