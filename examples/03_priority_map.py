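"""Run the full prioritization pipeline and print the priority map summary.

Cave scores are aggregated onto a 40 x 30 grid (per-cell maximum of each
attribute layer), the four layers are summed into a composite conservation
value (PiC), and occupied cells are split into four priority tiers by exact
natural-breaks classification.  All artifacts (attributes, scores, cell
table, GeoJSON map, JSON report) land in ./scratch_priority_run.
"""

from karstprior import StudyConfig, run_pipeline, summarize_report

report = run_pipeline(
    StudyConfig(seed=42), simulate=True, out_dir="scratch_priority_run"
)
print(summarize_report(report))

# The "extreme" tier marks the cells whose caves combine high richness,
# endemism, and surrounding land-use pressure — the candidate priority
# areas for protection.  priority.geojson holds the mappable polygons.
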