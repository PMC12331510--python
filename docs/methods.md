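# Methods

## The question

When a group of autonomous agents is trained or evolved with a single
shared score, the choice of how individual outcomes are collapsed into
that score changes both how well the group performs and how evenly the
spoils are divided.  `minforage` implements a four-agent foraging task and
compares three aggregation operators over the agents' individual food
counts `F_0..F_3`:

- `W_MEAN = (1/4) Σ F_i` — pooled and split evenly;
- `W_MIN  = min_i F_i`  — the group is judged by its weakest member;
- `W_MAX  = max_i F_i`  — the group is judged by its strongest member
  (a control that rewards monopolisation).

The hypothesis under test is that the weakest-member score matches the
MEAN score's group performance while producing a much fairer division of
food, and outperforms the MAXIMUM control.  Fairness is quantified by the
**despotic index**: sort each group's four final hauls in descending
order, average each rank across replicates, and fit a least-squares line
against rank 0..3.  A slope of 0 is a perfectly even split; the more
negative the slope, the more despotic the distribution.  The closed form
for a single hoarder `(9,0,0,0)` is a slope of −2.7 tokens/rank.

## The foraging worlds

Both world dialects share the same economics: stepping onto a food tile
collects the token, stepping into another agent transfers one held token
from the mover to the occupant (a no-op if the mover holds none), walls
are silent no-ops, and total food (on-grid + held) is conserved by every
update.  The four agents act simultaneously; ties are resolved by
processing agents in ascending index order, which makes every trajectory
a pure function of the seed and the action sequence.

- **GA dialect**: 16×16 room, 100 updates per episode, agents start in
  the four corners facing North, partially observed.  Each agent senses
  7 bits: a 2-bit code for the tile ahead (empty/food/agent/wall), the
  3 beep flags the other agents raised on the previous update, and its
  own food count saturated at 3.  Its actuators are 2 movement bits
  (nothing / turn left / turn right / forward, where forward doubles as
  eat-or-give) and 1 beep bit.
- **Q dialect**: 8×8 room, 50 steps per episode, fully observed, moves in
  the four cardinal directions.  The learning state is the 64-tile grid
  with empty = 0, food = 1, other agents = −1 and (for a per-agent view)
  the controlled agent = −0.5.

Default food density is 1.0 — a food-saturated room (60 tokens on the 8×8
board, 252 on the 16×16), regenerating never.  Starting all GA agents
facing North is a deliberate symmetry break: with rotationally symmetric
headings four clones of one genome would behave identically up to
rotation and every scheme would trivially produce a flat distribution;
the shared North heading gives the corners genuinely different local
problems, which is what lets the reward schemes differentiate.

## Markov Brains and the genetic algorithm

Controllers in the GA dialect are Markov Brains: networks of 1–4-input /
1–4-output deterministic or probabilistic logic gates wired over 19
binary nodes (7 sensors, 9 hidden, 3 actuators), decoded from a
byte-string genome at every occurrence of the start codon (42, 213).
Hidden nodes carry state between updates only through gates that read and
write them, which is sufficient for latches and counters.  Multiple
writers to one node combine by OR.  Fresh random genomes are seeded with
start codons, since a uniform byte string of a few hundred sites would
almost surely decode to an empty brain.

Mutation applies per-site point resampling (default 0.005/site), and
per-genome segment deletion (p = 0.02) and duplication (p = 0.05) with
lengths clamped to configured bounds.  Selection is pure roulette wheel
on the group score, no elitism, no crossover.  Two group formations are
compared:

- **group-level selection** (`GroupLS`): each genome is cloned into a
  group of four; the group score credits the one parent;
- **inclusive fitness** (`InclW`): the population is shuffled and
  partitioned into groups of four distinct members, four times per
  generation; each member accumulates the score of every group it joined.
  Summing (rather than averaging) over the four evaluations is
  monotone-equivalent for roulette selection.

Per-replicate reporting: the per-generation log records the mean and best
group food (sum of the four members' hauls) over all groups evaluated
that generation; the final distribution is the best-scoring group's food
vector in the last generation, i.e. the evolved behaviour rather than the
population average over mutants.

## Q-learning

The two control architectures mirror the two evolutionary regimes: one
**centralized** policy over the 256 = 4⁴ joint actions, or four
**decentralized** policies over 4 actions each.  In both cases every
policy is trained on the same scheme-aggregated reward — the aggregation
of the per-step food deltas — so the reward scheme remains the only group
signal (individual rewards would collapse all three schemes into selfish
learning).  A terminal-only reward mode (aggregate of final totals on the
last step) is available behind `reward_mode`, with per-step shaping the
default; for MEAN the episode sum of per-step rewards equals the score of
the final totals, for MIN/MAX per-step shaping is an approximation of the
episode objective.

Action values live in a dictionary-backed sparse table keyed by a compact
byte encoding of the state; for the centralized table the ordered agent
positions are appended to the key so permuted agent configurations never
alias.  Unseen states materialise uniform-random value vectors in [0, 1)
from the run's seeded stream.  Every access stamps the entry with the
current epoch and entries unused for `prune_ttl` (default 2,000) epochs
are dropped; because each epoch restarts from the same layout and corner
positions, a converged policy revisits the same state chain and pruning
cannot alter its greedy trajectory — a property the tests check directly.

Defaults follow the canonical setup: α = 0.8, ε from 1.0 decaying
multiplicatively at 0.999/epoch, replay batches of 2,000 from a
50,000-capacity FIFO buffer, 50-step epochs, 10,000 epochs, 40
replicates.  The discount γ is not part of that canon; 0.9 is used as the
standard choice and is exposed in the config, as is an ε floor of 0.01 so
scaled-down runs never shut exploration off entirely.  Replay samples
without replacement within a batch (with-replacement available by flag).
Decentralized agents keep separate replay buffers.

End-of-run performance is measured by one exploitation-only (ε = 0)
episode with the trained tables, with first-index tie-breaking so the
rollout is deterministic; this evaluates the learned policy itself rather
than a mixture of policy and residual exploration noise.

## Statistics

Conditions are compared with the two-sample Kolmogorov–Smirnov test on
the per-replicate group food scores, chosen because the outcome
distributions are small-sample and often multimodal.  Every condition is
tested against the two group-level baselines (`GroupLS-MEAN`,
`GroupLS-MINIMUM`), excluding self-pairs: with six conditions that is
m = 6·2 − 2 = 10 tests, and significance uses the Bonferroni-corrected
threshold 0.01/10 (the baseline-vs-baseline pair is evaluated from both
sides rather than deduplicated — the only counting that reaches ten).
Asymptotic p-values are the default; the exact null distribution is
available for small samples.  Ranked food profiles carry 95%
percentile-bootstrap confidence intervals (10,000 resamples, seeded); at
confidence level 0 the interval collapses to the mean by definition.

## Problem scales

`full` scale reproduces the full-size design (GA: 100 genomes,
50,000 generations; QL: 10,000 epochs, batch 2,000; 40 replicates).
`desk` scale is the package's reduced design for a single CPU:

| knob | full | desk |
|---|---|---|
| GA population / generations | 100 / 50,000 | 20 / 60 |
| genome length / gate cap | 5,000 / unlimited | 400 / 12 |
| QL epochs / batch | 10,000 / 2,000 | 400 / 500 |
| QL ε decay per epoch | 0.999 | 0.999^(10000/400) |
| replicates | 40 | 10 |

The desk ε decay compresses the same exploration→exploitation profile
into the shorter run rather than truncating it at ε ≈ 0.67, which would
evaluate a policy that never got to exploit.  Replicate seeds are derived
from the master seed through independent seed sequences, so streams are
disjoint and every output file is reproducible byte for byte.

## What desk scale does and does not show

At desk scale the qualitative orderings emerge clearly: MINIMUM and MEAN
clonal groups out-forage MAXIMUM and the generation-0 baseline, the
despotic slope steepens MINIMUM < MEAN < MAXIMUM, centralized control
beats decentralized under every scheme, and centralized MINIMUM is
flatter than centralized MAXIMUM.  One full-scale phenomenon is only
partially visible: extreme hoarding under `GroupLS-MAXIMUM` (one agent
holding half or more of the group's food) relies on evolved give-food /
coordination behaviour that needs far more evolutionary time; its
precursor is measurable — the top-rank share of group food rises with
generation budget (≈0.42 at 60 generations, ≈0.46 at 200, with single
replicates reaching 0.78) — but the averaged share stays below one half
at desk budgets.

The synthetic worlds are also idealisations: food never regenerates, the
room is rectangular with exactly four agents, and depositing food onto
empty tiles is deliberately not modelled (the forward action transfers
food only when an agent is directly ahead).  Results here are statements
about this task family, not about richer environments.

## Numerical and degenerate-input choices

- Aggregation validates vector length (4 by default) and is exact for
  MIN/MAX; MEAN inherits float summation order.
- `despotic_index` forces the slope to exactly 0 for constant profiles.
- Transfers floor at zero inventory; episodes refuse to step past their
  length; empty replay buffers and sub-2 samples are rejected.
- Greedy action selection breaks ties uniformly at random during
  training but deterministically (first index) during evaluation
  rollouts.
- Probabilistic gate rows normalise raw table bytes; an all-zero row
  falls back to the uniform distribution.
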