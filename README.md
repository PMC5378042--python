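# pedcds — pediatric cardiovascular risk-reduction decision support

`pedcds` is a desk-scale clinical decision support (CDS) library and CLI for
pediatric preventive cardiology. It operationalizes integrated
cardiovascular-risk guidance for children and adolescents — family history,
nutrition and diet, physical activity, tobacco exposure, lipids, overweight
and obesity, blood pressure, and other risk conditions — as an executable,
testable artifact for clinical informaticists and CDS developers:

* **Percentile math.** BMI-for-age via the LMS method
  (`z = ((x/M)^L − 1)/(L·S)`, log branch at `L = 0`; percentile `100·Φ(z)`)
  against CDC-dialect growth-reference CSVs, and blood-pressure percentiles
  by piecewise-linear inversion of NHLBI-style knot tables keyed by sex, age
  in years and height-percentile column.
* **A declarative rulebase.** Guideline content — typed data elements,
  trigger → recommendation rules with half-open age bands in months,
  evidence grades A–F, supportive actions, lipid/BMI cutpoints — lives in a
  schema-validated YAML document, not in code. A representative rulebase
  (58 rules across all eight risk domains, using the standard published
  cutpoints) ships with the package.
* **A three-valued rule engine.** Triggers are conjunction/disjunction trees
  over predicates evaluated with Kleene logic: a question answered
  "unknown" never fires a definite rule; missingness is targeted explicitly
  with an `is_unknown` comparator. Fired recommendations are deduplicated
  and emitted in a fixed domain order, byte-reproducibly.
* **A validation harness.** For every numeric boundary (trigger thresholds
  *and* age-band edges) it generates probes one unit below, at, and above
  the threshold with all sibling conditions satisfied, duplicated per tool
  context (990 cases for the shipped rulebase), plus a frozen suite of 75
  multi-domain scenarios, plus an independent brute-force trigger oracle and
  comparator-mutation testing.

## Worked example

```python
import datetime as dt
from pedcds import bmi_assessment, default_reference_library, packaged_rulebase

library = default_reference_library(seed=0)   # synthetic closed-form references
rulebase = packaged_rulebase()
result = bmi_assessment(dob=dt.date(2006, 4, 2), encounter_date=dt.date(2016, 8, 20),
                        sex="male", height=1.38, weight=44.5,
                        library=library, thresholds=rulebase.bmi_thresholds())
```

prints (via `python examples/bmi_percentile.py`):

```
age            : 124.6 months (10 y)
BMI            : 23.37 kg/m^2
z-score        : +2.841
percentile     : 99.8
weight status  : obese
```

The patient's exact age in months selects the LMS row (month-midpoint
convention, no interpolation); the BMI of 23.37 kg/m² sits 2.84 standard
units above the reference median for 10-year-old boys, i.e. the 99.8th
percentile, which the rulebase's 95th-percentile cutpoint classifies as
obese. `examples/` contains one script per capability (BMI, BP, lipids, the
integrated screener, rulebase validation), each printing what it computes.

The same operations are available from a shell, with explicit session files
carrying data between tools the way the four modules share previously
entered values:

```sh
pedcds bmi patient.json --session visit.json
pedcds lipid labs.json --session visit.json   # sees the carried-over demographics
pedcds assess patient.json --format text
pedcds validate                               # boundary cases + scenarios + age bands
pedcds fixtures --out fixtures/ --seed 7      # deterministic synthetic references
pedcds matrix --out matrix.csv                # variable x recommendation matrix
pedcds clear --session visit.json             # the trashcan action
```

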