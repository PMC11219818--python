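"""Rank the 14 detector variants with the composite performance index.

Each variant contributes four metrics: mAP@0.5 and mAP@.5:.95 (accuracy,
percent), GFLOPs and parameter count in millions (cost).  Every column is
min-max normalized over the candidate set and combined with weights
0.7 / 0.2 / -0.05 / -0.05, so a variant at the minimum of every column
scores 0 and the best possible score is 0.9.  Higher score = better
accuracy per unit of model cost.
"""

from spikedet.gpi import compute_gpi, format_ranked_table, rank_models, reference_table

table = reference_table()
print(format_ranked_table(table))

ranked = rank_models(compute_gpi(table), table)
best = ranked[0]
print(f"\nBest accuracy/cost trade-off: {best.name} "
      f"(score {best.score:.4f}; printed as {best.score:.2f})")
print("The two variants printing 0.84 are separated by their unrounded "
      f"scores: {ranked[0].score:.4f} vs {ranked[1].score:.4f}.")
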