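"""Synthetic cohort end to end: generate, compute doses, summarize.

Generates a 25-trio synthetic cohort (five per ascertainment category),
runs the full dose pipeline at reduced realization counts, and prints the
paternal dose-interval table for the DOB-38 window plus the dose vs
birth-year correlation.
"""

from doserecon import CohortConfig, PipelineConfig, generate_cohort, run_pipeline
from doserecon.summary import render_table

config = CohortConfig(
    n_trios={"A": 5, "B": 5, "C": 5, "D": 5, "E": 5}, n_settlements=12
)
bundle = generate_cohort(config, seed=11)
print(f"generated {len(bundle.trios)} trios, {len(bundle.children)} children, "
      f"{len(bundle.itineraries)} mission itineraries, "
      f"{len(bundle.pripyat_timelines)} Pripyat timelines")

result = run_pipeline(
    bundle, PipelineConfig(n_mission=500, n_residential=100, seed=11)
)
print(f"dose table: {len(result.doses)} rows "
      f"(child x parent x pathway x window)\n")

print(render_table(result.summaries["total_father"],
                   "children by paternal DOB-38 dose interval (mGy):"))
print()
for key, (r, p) in result.correlations.items():
    print(f"dose vs birth year, {key:14s}: r = {r:+.3f}  (p = {p:.3g})")
# Mission doses dominate the paternal totals; the negative correlation with
# birth year appears because most exposure occurred in 1986-1990, so
# children born later sit farther from their parents' exposure period.
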