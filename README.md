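# minforage

Weakest-member group rewards in a multi-agent foraging world.

When four agents forage together and are trained on a single shared
score, the way individual outcomes are collapsed into that score decides
both how much the group collects and how fairly it is divided.
`minforage` implements the comparison between three aggregation schemes
over the agents' individual food counts `F_0..F_3`:

```
W_MEAN = (1/4) Σ F_i        pooled and split evenly
W_MIN  = min(F_0..F_3)      judged by the weakest member
W_MAX  = max(F_0..F_3)      judged by the strongest member (control)
```

under two optimisers and two group structures:

- a **genetic algorithm** over evolvable logic-gate networks
  (Markov Brains), with *group-level selection* (clonal groups) or
  *inclusive fitness* (randomly composed groups);
- **sparse tabular Q-learning** with *centralized* control (one policy,
  256 joint actions) or *decentralized* control (four independent
  policies), epsilon-decay exploration, experience replay and TTL-pruned
  dictionary Q-tables.

Fairness is summarised by the **despotic index** — the least-squares
slope of the rank-sorted mean food per agent (0 = perfectly fair,
steeply negative = one agent monopolises).  Conditions are compared with
two-sample Kolmogorov–Smirnov tests under Bonferroni correction.  The
package is aimed at researchers in multi-agent reinforcement learning
and evolutionary dynamics who want a small, fully reproducible testbed
for reward-scheme design.

## Worked example

Evolve clonal groups under the weakest-member score
(`examples/evolve_weakest_link.py`):

```python
from minforage.ga import GAConfig, evolve
from minforage.markov_brain import MutationRates

config = GAConfig(regime="group_ls", scheme="minimum", population_size=16,
                  generations=30, genome_length=400, max_gates=12,
                  rates=MutationRates(segment_range=(8, 64),
                                      length_bounds=(100, 1200)),
                  seed=7)
result = evolve(config)
```

prints

```
generation   0: mean group food   30.9  best group  122.0
generation  15: mean group food  114.5  best group  152.0
generation  30: mean group food  119.4  best group  164.0
final best group's per-agent food: [38, 52, 33, 41]
```

Mean group food climbs from the random-brain baseline (~31 of the 252
tokens in the room) to ~119 as selection rewards genomes whose
*worst-placed* clone still forages; the final best group's hauls are
close to even — the signature of the MINIMUM scheme.  Compare
`examples/qlearning_centralized.py`, where a single joint policy learns
the 8×8 world and its exploitation-only rollout collects 45 of the 60
available tokens, and `examples/compare_conditions.py`, which runs the
full 6-condition grid and prints the 10-test KS comparison table and
per-condition despotic profiles.

A thin CLI wraps the same machinery:

```bash
minforage run --engine ql --regime group_ls --scheme minimum --out results/
minforage compare --results results/
minforage despotic --results results/
```

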