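"""Sparse tabular Q-learning over the fully observed 8x8 foraging world.

Two control architectures are the reinforcement-learning analogues of the
two evolutionary regimes:

* **centralized** — one policy controls all four agents at once over the
  256 (= 4^4) joint actions; the group-level-selection analogue.
* **decentralized** — four independent policies, one per agent, each over
  its own 4 cardinal moves; the inclusive-fitness analogue.  Every policy
  is trained on the same scheme-aggregated group reward, so the reward
  scheme remains the only group signal.

Because the dense state space (4^64 board states) is unstorable, action
values live in a hash-keyed sparse table: an unseen state materialises a
uniform-random value vector on first query, every access stamps the entry
with the current epoch, and entries untouched for a time-to-live number of
epochs are pruned.  Exploration is epsilon-greedy with multiplicative
per-epoch decay, and learning happens by experience replay: transitions go
into a bounded FIFO buffer and each epoch a random batch is replayed
through the Bellman update

    Q(s,a) <- Q(s,a) + alpha * (r + gamma * max_a' Q(s',a') - Q(s,a)).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .env import CENTRALIZED, ActionQ, QWorld, build_world, encode_state_q
from .rewards import Scheme, aggregate, step_reward

__all__ = [
    "SparseQTable",
    "Experience",
    "QLConfig",
    "bellman_update",
    "choose_action",
    "replay_train",
    "prune",
    "encode_joint_action",
    "decode_joint_action",
    "train",
    "greedy_rollout",
    "greedy_trajectory",
    "QLResult",
    "N_JOINT_ACTIONS",
]

N_MOVES = 4
N_JOINT_ACTIONS = N_MOVES**4  # 256


class SparseQTable:
    """Dictionary-backed Q matrix with last-access timestamps.

    Keys are hashable state encodings; values are float vectors of fixed
    length (4 for a per-agent policy, 256 for the joint policy).  A state
    queried for the first time receives a uniform-random value vector in
    [0, 1) drawn from the table's own seeded stream, and every query
    refreshes the state's last-access epoch.
    """

    def __init__(self, n_actions: int, rng: np.random.Generator):
        self.n_actions = n_actions
        self.entries: dict = {}
        self.last_access: dict = {}
        self._rng = rng

    def __len__(self) -> int:
        return len(self.entries)

    def values(self, key, epoch: int) -> np.ndarray:
        v = self.entries.get(key)
        if v is None:
            v = self._rng.random(self.n_actions)
            self.entries[key] = v
        self.last_access[key] = epoch
        return v

    def peek(self, key) -> np.ndarray | None:
        """Read without materialising or touching the timestamp."""
        return self.entries.get(key)

    def checkpoint(self) -> list[dict]:
        """JSON-serialisable snapshot (one record per state)."""
        return [
            {"state_key": k.hex() if isinstance(k, bytes) else k,
             "values": self.entries[k].tolist(),
             "last_access": self.last_access[k]}
            for k in self.entries
        ]


@dataclass(frozen=True)
class Experience:
    """One replayable transition (s_t, a_t, r_t, s_{t+1})."""

    s: object
    a: int
    r: float
    s_next: object


@dataclass(frozen=True)
class QLConfig:
    control: str = "centralized"  # or "decentralized"
    scheme: Scheme = Scheme.MINIMUM
    alpha: float = 0.8
    gamma: float = 0.9
    epsilon0: float = 1.0
    epsilon_decay: float = 0.999
    epsilon_min: float = 0.01
    steps_per_epoch: int = 50
    epochs: int = 10_000
    batch: int = 2_000
    buffer_capacity: int = 50_000
    prune_ttl: int = 2_000
    food_density: float = 1.0
    reward_mode: str = "per_step"  # or "terminal"
    seed: int = 0

    def __post_init__(self):
        if self.control not in ("centralized", "decentralized"):
            raise ValueError(f"unknown control {self.control!r}")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha in (0, 1]")
        if not 0 <= self.gamma < 1:
            raise ValueError("gamma in [0, 1)")
        if not 0 < self.epsilon_decay <= 1:
            raise ValueError("epsilon_decay in (0, 1]")
        if self.reward_mode not in ("per_step", "terminal"):
            raise ValueError("reward_mode is 'per_step' or 'terminal'")
        object.__setattr__(self, "scheme", Scheme.coerce(self.scheme))


def bellman_update(q_sa: float, r: float, max_next: float, alpha: float, gamma: float) -> float:
    """One-step temporal-difference target blend.

    Algebraically identical to ``(1 - alpha) * q_sa + alpha * (r + gamma *
    max_next)``; both forms agree to floating tolerance.
    """
    return q_sa + alpha * (r + gamma * max_next - q_sa)


def choose_action(
    table: SparseQTable, key, epsilon: float, rng: np.random.Generator, epoch: int = 0
) -> int:
    """Epsilon-greedy action with uniform random tie-breaking."""
    if not 0 <= epsilon <= 1:
        raise ValueError("epsilon in [0, 1]")
    v = table.values(key, epoch)
    if epsilon > 0 and rng.random() < epsilon:
        return int(rng.integers(table.n_actions))
    best = np.flatnonzero(v == v.max())
    return int(best[rng.integers(best.size)]) if best.size > 1 else int(best[0])


def replay_train(
    table: SparseQTable,
    buffer: deque,
    config: QLConfig,
    rng: np.random.Generator,
    epoch: int = 0,
    with_replacement: bool = False,
) -> SparseQTable:
    """Replay a random batch of experiences through the Bellman update.

    Samples ``min(batch, len(buffer))`` transitions uniformly (without
    replacement by default); the sampling order is independent of the
    insertion order.
    """
    if not buffer:
        raise ValueError("replay buffer is empty")
    n = len(buffer)
    size = min(config.batch, n) if not with_replacement else config.batch
    idx = rng.choice(n, size=size, replace=with_replacement)
    alpha, gamma = config.alpha, config.gamma
    for i in idx:
        exp = buffer[int(i)]
        v = table.values(exp.s, epoch)
        max_next = table.values(exp.s_next, epoch).max()
        v[exp.a] = bellman_update(v[exp.a], exp.r, max_next, alpha, gamma)
    return table


def prune(table: SparseQTable, current_epoch: int, ttl: int) -> SparseQTable:
    """Drop every entry unused for at least ``ttl`` epochs (in place)."""
    if ttl <= 0:
        raise ValueError("ttl must be positive")
    stale = [k for k, t in table.last_access.items() if current_epoch - t >= ttl]
    for k in stale:
        del table.entries[k]
        del table.last_access[k]
    return table


def encode_joint_action(moves) -> int:
    """Base-4 pack of four cardinal moves; agent 0 is the least-significant
    digit, digit values 0=N, 1=S, 2=E, 3=W."""
    if len(moves) != 4:
        raise ValueError("four moves required")
    idx = 0
    for i, m in enumerate(moves):
        idx += int(ActionQ(m)) * (4**i)
    return idx


def decode_joint_action(index: int) -> tuple[ActionQ, ActionQ, ActionQ, ActionQ]:
    """Inverse of :func:`encode_joint_action` over 0..255."""
    if not 0 <= index < N_JOINT_ACTIONS:
        raise ValueError("joint action index out of range")
    return tuple(ActionQ(index // (4**i) % 4) for i in range(4))  # type: ignore[return-value]


def _fresh_world(config: QLConfig) -> QWorld:
    # same seed every epoch: consistent starting layout, the premise of
    # TTL pruning
    return build_world("Q", config.seed, config.food_density)


def _episode(
    config: QLConfig,
    tables: list[SparseQTable],
    buffers: list[deque],
    epsilon: float,
    rng: np.random.Generator,
    epoch: int,
    record: bool = True,
    world_factory=None,
) -> int:
    """One foraging episode; returns the group's food haul.

    With ``record`` False no experience is stored (pure evaluation)."""
    world = (world_factory or _fresh_world)(config)
    centralized = config.control == "centralized"
    n = world.n_agents
    pending: list[tuple] = []  # (keys, actions, reward) awaiting next state
    keys = (
        [encode_state_q(world, CENTRALIZED).key]
        if centralized
        else [encode_state_q(world, i).key for i in range(n)]
    )
    for _ in range(config.steps_per_epoch):
        if centralized:
            a = choose_action(tables[0], keys[0], epsilon, rng, epoch)
            moves = decode_joint_action(a)
            actions = [a]
        else:
            actions = [
                choose_action(tables[i], keys[i], epsilon, rng, epoch) for i in range(n)
            ]
            moves = [ActionQ(a) for a in actions]
        delta = world.step(moves)
        next_keys = (
            [encode_state_q(world, CENTRALIZED).key]
            if centralized
            else [encode_state_q(world, i).key for i in range(n)]
        )
        if record:
            if config.reward_mode == "per_step":
                r = step_reward(delta, config.scheme)
            else:
                r = 0.0
                if world.time == config.steps_per_epoch:
                    r = aggregate(world.food, config.scheme, n_agents=n)
            for t, (k, a) in enumerate(zip(keys, actions)):
                buffers[t].append(Experience(k, a, r, next_keys[t]))
        keys = next_keys
    return sum(world.food)


@dataclass
class QLResult:
    config: QLConfig
    trajectory: list[dict]  # {epoch, group_food, epsilon, table_size}
    final_food: list[int]  # greedy-evaluation per-agent food, end of training
    tables: list[SparseQTable]


def train(config: QLConfig, world_factory=None) -> QLResult:
    """Train policies for ``config.epochs`` epochs of 50-step foraging.

    Each epoch runs one episode under the current epsilon (logging the
    group food it collects), pushes its transitions into the replay
    buffer(s), replays a batch through the Bellman update, decays epsilon
    multiplicatively down to its floor, and prunes stale table entries.
    The final distribution is measured by one greedy (epsilon = 0) episode
    with the trained policy.
    """
    rng = np.random.default_rng(config.seed)
    centralized = config.control == "centralized"
    factory = world_factory or _fresh_world
    n_agents = factory(config).n_agents
    n_tables = 1 if centralized else n_agents
    n_actions = N_JOINT_ACTIONS if centralized else N_MOVES
    tables = [
        SparseQTable(n_actions, np.random.default_rng(rng.integers(2**31)))
        for _ in range(n_tables)
    ]
    buffers = [deque(maxlen=config.buffer_capacity) for _ in range(n_tables)]
    epsilon = config.epsilon0
    trajectory: list[dict] = []
    for epoch in range(config.epochs):
        food = _episode(config, tables, buffers, epsilon, rng, epoch, world_factory=factory)
        for t in range(n_tables):
            replay_train(tables[t], buffers[t], config, rng, epoch)
        prune_all(tables, epoch, config.prune_ttl)
        trajectory.append(
            {
                "epoch": epoch,
                "group_food": food,
                "epsilon": epsilon,
                "table_size": sum(len(t) for t in tables),
            }
        )
        epsilon = max(config.epsilon_min, epsilon * config.epsilon_decay)
    final_food = greedy_rollout(config, tables, world_factory=factory)
    return QLResult(config, trajectory, final_food, tables)


def prune_all(tables: list[SparseQTable], epoch: int, ttl: int) -> None:
    for t in tables:
        prune(t, epoch, ttl)


def greedy_rollout(
    config: QLConfig, tables: list[SparseQTable], world_factory=None
) -> list[int]:
    """Per-agent food from one exploitation-only episode (epsilon = 0).

    Ties are broken by the first maximal action so the rollout is
    deterministic for a fixed table — the property pruning must preserve.
    """
    world = (world_factory or _fresh_world)(config)
    centralized = config.control == "centralized"
    n = world.n_agents
    for _ in range(config.steps_per_epoch):
        if centralized:
            v = tables[0].peek(encode_state_q(world, CENTRALIZED).key)
            a = int(v.argmax()) if v is not None else 0
            moves = decode_joint_action(a)
        else:
            moves = []
            for i in range(n):
                v = tables[i].peek(encode_state_q(world, i).key)
                moves.append(ActionQ(int(v.argmax()) if v is not None else 0))
        world.step(moves)
    return list(world.food)


def greedy_trajectory(
    config: QLConfig, tables: list[SparseQTable], world_factory=None
) -> list[tuple]:
    """Deterministic move sequence of the exploitation-only episode.

    Used to verify that pruning stale states leaves a converged policy's
    behaviour untouched."""
    world = (world_factory or _fresh_world)(config)
    centralized = config.control == "centralized"
    n = world.n_agents
    moves_log: list[tuple] = []
    for _ in range(config.steps_per_epoch):
        if centralized:
            v = tables[0].peek(encode_state_q(world, CENTRALIZED).key)
            moves = decode_joint_action(int(v.argmax()) if v is not None else 0)
        else:
            moves = tuple(
                ActionQ(
                    int(vv.argmax())
                    if (vv := tables[i].peek(encode_state_q(world, i).key)) is not None
                    else 0
                )
                for i in range(n)
            )
        moves_log.append(tuple(moves))
        world.step(moves)
    return moves_log
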