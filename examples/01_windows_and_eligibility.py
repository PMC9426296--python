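"""Preconception exposure windows and cohort eligibility.

Builds the two integration windows for one child and shows the calendar
rules: windows run from the accident date (1986-04-26) to 51 and 38 weeks
before the child's date of birth, a child is eligible if born 46 weeks or
later after the accident, and cleanup-mission exposure additionally
truncates at the legal end of cleanup activities (1990-12-31).
"""

import datetime as dt

from doserecon import (
    ACCIDENT_DATE,
    Child,
    WindowKind,
    dose_category,
    is_eligible,
    mission_cutoff,
)

child = Child(id="C1", trio_id="T1", dob=dt.date(1988, 2, 10))
w51 = child.window(WindowKind.DOB51)
w38 = child.window(WindowKind.DOB38)

print(f"accident date        : {ACCIDENT_DATE}")
print(f"child DOB            : {child.dob}  (eligible: {is_eligible(child.dob)})")
print(f"DOB-51 window end    : {w51.end}  ({w51.length_days} days of exposure)")
print(f"DOB-38 window end    : {w38.end}  ({w38.length_days} days of exposure)")
print(f"window gap           : {(w38.end - w51.end).days} days (spermatid stage)")

cutoff = mission_cutoff(w38.end, mission_end=dt.date(1991, 6, 30))
print(f"mission dose cutoff  : {cutoff} (earliest of window / mission / 1990-12-31)")

print(f"dose interval of 11 mGy: {dose_category(11.0)!r}")
# The 91-day gap is the dose-relevant difference between the two windows:
# a father exposed inside it has DOB-38 dose > DOB-51 dose.
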