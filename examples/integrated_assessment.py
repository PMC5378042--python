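"""Run the integrated risk screener over a full patient session.

Builds a session spanning every module (demographics, BP readings, a lipid
panel, lifestyle and family-history answers), derives all facts, evaluates
the rulebase with three-valued logic, and prints the deduplicated
recommendations with their evidence grades.
"""

import datetime as dt

from pedcds import (Anthropometrics, BPEntry, LipidPanel, PatientSession,
                    RiskFactorProfile, default_reference_library, packaged_rulebase,
                    run_assessment)

session = PatientSession(
    anthropometrics=Anthropometrics(
        dob=dt.date(2004, 4, 2), encounter_date=dt.date(2016, 5, 10), sex="male",
        height=1.52, weight=62.0, bmi_change_category="excessive_increase"),
    bp=BPEntry(readings=[(128, 83), (126, 81)], method="oscillometry"),
    lipid_panel=LipidPanel(sample_type="fasting", total_cholesterol=212,
                           hdl=39, ldl=138, triglycerides=145),
    risk=RiskFactorProfile(conditions=("none",), activity_level="sedentary",
                           smokes="no", smoke_free_home="no", parent_obese="yes",
                           family_history_cvd="yes"))

rulebase = packaged_rulebase()
library = default_reference_library(seed=0)
result = run_assessment(session, rulebase, library, context="screener")

facts = result.patient_summary
print(f"BMI {facts['bmi']:.1f} kg/m^2 -> {facts['bmi_percentile']:.1f}th pct "
      f"({facts['bmi_category']})")
print(f"mean BP {facts['mean_systolic']:.0f}/{facts['mean_diastolic']:.0f} mmHg")
print(f"fired recommendations: {len(result.fired)}")
for rec in result.fired:
    print(f"  [{rec.grade}] {rec.recommendation_id}  (rules {', '.join(rec.rule_ids)})")
print()
print("Recommendations are deduplicated per id, ordered by risk domain; a")
print("question answered 'unknown' never fires a definite rule.")
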