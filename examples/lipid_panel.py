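"""Categorize a fasting lipid panel against the rulebase cutpoints.

Derives non-HDL cholesterol (TC - HDL), applies the age-appropriate
triglyceride bands, and labels each analyte acceptable / borderline / high
(low / borderline / acceptable for HDL, where low is the bad direction).
"""

import datetime as dt

from pedcds import LipidPanel, lipid_assessment, packaged_rulebase

rulebase = packaged_rulebase()
panel = LipidPanel(sample_type="fasting", total_cholesterol=212,
                   hdl=39, ldl=138, triglycerides=145)

result = lipid_assessment(panel, dob=dt.date(2004, 4, 2),
                          encounter_date=dt.date(2016, 5, 10), sex="female",
                          cutpoint_table=rulebase.lipid_cutpoint_table(age_months=145))

print(f"non-HDL (derived): {result.panel.non_hdl} mg/dL")
for analyte, label in sorted(result.categories.items()):
    print(f"{analyte:18s}: {label}")
print()
print("A value exactly at a cutpoint takes the more severe label; the")
print("triglyceride bands switch at age 10 (75/100 mg/dL before, 90/130 after).")
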