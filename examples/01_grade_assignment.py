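"""Assign 2017 ACC/AHA blood-pressure grades and inspect the ROI registry.

Run:  python examples/01_grade_assignment.py
"""

from kelmplus import aal_registry, grade_from_bp
from kelmplus.datamodel import GRADE_NAMES

# Group-mean pressures of four cohorts, one per grade
cohort_means = [(109.1, 69.64), (122.9, 72.4), (126.2, 83.6), (153.8, 88.4)]
print("SBP/DBP (mmHg) -> grade")
for sbp, dbp in cohort_means:
    g = grade_from_bp(sbp, dbp)
    print(f"  {sbp:6.1f} / {dbp:6.2f} -> grade {g} ({GRADE_NAMES[g]})")
# The third pair shows the and/or rule: SBP 126.2 alone would be 'elevated',
# but DBP 83.6 is in the 80-89 stage-1 band, and the higher grade wins.

registry = aal_registry()
n_sub = sum(not r.cortical for r in registry)
print(f"\nAAL registry: {len(registry)} ROIs, {n_sub} sub-cortical "
      f"(excluded from the thickness network by default, leaving {len(registry) - n_sub}).")
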