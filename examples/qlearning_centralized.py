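"""Centralized Q-learning of a four-agent group on the 8x8 world.

One policy chooses a joint action (256 = 4^4 combinations of cardinal
moves) for the whole group, is rewarded per step by the scheme-aggregated
food deltas, and learns by experience replay over a sparse, pruned Q
table.  The epsilon schedule is compressed from the full-length run so the
policy is exploiting by the end of this short demonstration.
"""

from minforage.qlearning import QLConfig, train

config = QLConfig(
    control="centralized",
    scheme="minimum",
    epochs=300,
    batch=500,
    epsilon_decay=0.98,
    seed=1,
)
result = train(config)
for rec in result.trajectory[::60] + [result.trajectory[-1]]:
    print(
        f"epoch {rec['epoch']:>4}: group food {rec['group_food']:>2}  "
        f"epsilon {rec['epsilon']:.3f}  table states {rec['table_size']}"
    )
print(f"greedy-policy per-agent food: {result.final_food} "
      f"(group {sum(result.final_food)} of 60 available)")
# Training food starts near the random-walk level (~45 of 60 tokens in a
# saturated room) and the exploitation-only rollout at the end collects
# most of the board.
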