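"""Replay the validation methodology on the shipped rulebase.

Generates below/at/above probes for every numeric boundary (including age
band edges), runs them through the engine, replays the frozen scenario
suite, and checks the age bands for overlaps.
"""

from pedcds import packaged_rulebase, packaged_scenarios, validate_age_bands
from pedcds.validation import (generate_boundary_cases, run_scenarios,
                               run_single_expression_tests)

rulebase = packaged_rulebase()

cases = generate_boundary_cases(rulebase, step=1.0)
case_report = run_single_expression_tests(rulebase, cases)
print(case_report.to_text())

scen_report = run_scenarios(rulebase, packaged_scenarios())
print(scen_report.to_text())

bands = validate_age_bands(rulebase.rules, rulebase.age_coverage)
print(f"age-band overlaps: {len(bands.overlaps)}")
print()
print(f"{len(cases)} single-expression cases (3 per numeric boundary per tool")
print("context) and the frozen multi-domain scenarios must all pass; any")
print("age-band overlap between same-trigger rules would be listed above.")
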