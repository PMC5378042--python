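"""BMI-for-age percentile from an LMS growth reference.

Builds the synthetic reference library, assesses one 10-year-old, and prints
the BMI, its z-score and percentile, and the weight-status category the
rulebase thresholds (85th / 95th percentile) assign.
"""

import datetime as dt

from pedcds import bmi_assessment, default_reference_library, packaged_rulebase

library = default_reference_library(seed=0)
rulebase = packaged_rulebase()

result = bmi_assessment(
    dob=dt.date(2006, 4, 2), encounter_date=dt.date(2016, 8, 20),
    sex="male", height=1.38, weight=44.5,
    library=library, thresholds=rulebase.bmi_thresholds())

print(f"age            : {result.exact_months:.1f} months ({result.age_years} y)")
print(f"BMI            : {result.bmi:.2f} kg/m^2")
print(f"z-score        : {result.z:+.3f}")
print(f"percentile     : {result.percentile:.1f}")
print(f"weight status  : {result.category}")
print()
print("The percentile is 100*Phi(z) with z from the LMS transform at the")
print("patient's (sex, age-month) reference row; 'overweight' starts at the")
print("85th percentile and 'obese' at the 95th, inclusive.")
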