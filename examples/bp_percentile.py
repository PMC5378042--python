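"""Blood-pressure percentile by inverting the reference knot table.

Averages three readings, snaps the patient's height percentile to the
nearest table column, and inverts the monotone percentile->mmHg knot
function per channel.
"""

import datetime as dt

from pedcds import BPEntry, bp_assessment, default_reference_library

library = default_reference_library(seed=0)

entry = BPEntry(readings=[(112, 70), (110, 68), (117, 75)], method="auscultation")
result = bp_assessment(
    dob=dt.date(2006, 4, 2), encounter_date=dt.date(2016, 8, 20),
    sex="male", entry=entry, library=library, height=1.41)

sex, age_years, height_knot = result.reference_row_key
print(f"mean BP        : {result.mean_systolic:.1f} / {result.mean_diastolic:.1f} mmHg")
print(f"reference row  : sex={sex}, age={age_years} y, height column={height_knot:g}th")
print(f"systolic pct   : {result.systolic_percentile:.1f}")
print(f"diastolic pct  : {result.diastolic_percentile:.1f}")
print()
print("Percentiles come from piecewise-linear inversion between table knots;")
print("values outside the knot span are censored (below_range/above_range),")
print("never extrapolated.")
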