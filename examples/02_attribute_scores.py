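"""Compute per-cave attributes and category scores.

Each cave is described by four criteria — non-troglobite richness (nTS),
troglobiont richness (TbS), stenoendemic count (EnD), and distinct impact
types within a 250 m buffer (VuL) — each binned into Low/Average/High/
Extreme and weighted 100/250/500/1000 (0 when absent).
"""

from karstprior import GeneratorParams, attribute_table, generate_dataset
from karstprior.scoring import score_table

dataset = generate_dataset(GeneratorParams(seed=42))
attrs = attribute_table(dataset.caves, dataset.occurrences, dataset.impacts)
scores, intervals = score_table(attrs)

print(f"nTS equal intervals over [{intervals.vmin}, {intervals.vmax}]: "
      f"upper bounds {list(intervals.uppers)}")
print()
print(scores.head(8).to_string(index=False))
print()
print(f"score totals range: {scores['total'].min()} .. {scores['total'].max()}")

# A cave's total (0..4000) sums its four attribute weights; the interval
# bounds are recomputed from this dataset's observed richness range.
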