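"""Group reward schemes and the despotic index on toy food vectors.

A group of four foragers is scored by one number W: the MEAN of their
individual hauls, the MINIMUM (the weakest member) or the MAXIMUM (the
strongest).  The despotic index is the least-squares slope of the
rank-sorted per-agent haul: 0 means a perfectly fair split, steeply
negative means one agent monopolises the food.
"""

from minforage import Scheme, aggregate, despotic_index

food = [3, 5, 2, 6]
print(f"food vector {food}")
for scheme in Scheme:
    print(f"  W_{scheme.name:<8} = {aggregate(food, scheme):g}")

fair = [[5, 5, 5, 5], [6, 5, 5, 4]]
despotic = [[9, 1, 0, 0], [8, 2, 1, 0]]
for label, reps in [("fair", fair), ("despotic", despotic)]:
    prof = despotic_index(reps)
    print(
        f"{label:>9}: ranked means {prof.ranked_means} "
        f"slope {prof.slope:+.2f} rank-1 share {prof.rank1_share:.2f}"
    )
# The slope is the fairness summary: the despotic group concentrates ~80%
# of the food in one agent and its profile falls ~3 tokens per rank.
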