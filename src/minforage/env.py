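"""Foraging grid worlds.

Two dialects of the same food-collection task:

* **GA dialect** — a 16x16 room, four agents starting in the corners, each
  with a heading, a one-bit "beep" communication channel and a partial
  (egocentric) view: the tile directly ahead, the beeps of the other agents
  from the previous update, and a saturating count of the food it carries.
* **Q dialect** — an 8x8 room observed in full.  Agents move in the four
  cardinal directions and the whole grid (plus agent positions) is the
  learning state.

Both dialects share the economics: walking onto a food tile collects the
token, walking into another agent transfers one token from the mover to the
occupant (if the mover holds any), walking into a wall does nothing, and the
total number of tokens (on the grid plus in inventories) is conserved by
every step.  Actions of the four agents are resolved sequentially in
ascending agent index, which makes every trajectory deterministic given the
seed and the action sequence.
"""

from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np

__all__ = [
    "Heading",
    "MoveGA",
    "ActionGA",
    "ActionQ",
    "ObservationGA",
    "StateQ",
    "GAWorld",
    "QWorld",
    "CENTRALIZED",
    "GA_EPISODE_LENGTH",
    "Q_EPISODE_LENGTH",
    "build_world",
    "observe_ga",
    "step_ga",
    "encode_state_q",
    "step_q",
    "total_food",
]

GA_SIDE = 16
Q_SIDE = 8
GA_EPISODE_LENGTH = 100
Q_EPISODE_LENGTH = 50

#: sentinel perspective for the joint (one-policy) state encoding
CENTRALIZED = "centralized"


class Heading(IntEnum):
    N = 0
    E = 1
    S = 2
    W = 3


# (drow, dcol) per heading, row 0 at the top
_DELTA = {Heading.N: (-1, 0), Heading.E: (0, 1), Heading.S: (1, 0), Heading.W: (0, -1)}


class MoveGA(IntEnum):
    """Movement component of a GA-dialect action.

    The integer values match the two-bit actuator encoding of the
    controller: 00=NOTHING, 01=LEFT, 10=RIGHT, 11=FORWARD.
    """

    NOTHING = 0
    LEFT = 1
    RIGHT = 2
    FORWARD = 3


@dataclass(frozen=True)
class ActionGA:
    move: MoveGA
    beep: bool = False


class ActionQ(IntEnum):
    """Cardinal move in the Q dialect; values are the base-4 digits of the
    joint-action index (agent 0 is the least-significant digit)."""

    N = 0
    S = 1
    E = 2
    W = 3


_DELTA_Q = {ActionQ.N: (-1, 0), ActionQ.S: (1, 0), ActionQ.E: (0, 1), ActionQ.W: (0, -1)}

# front-tile two-bit codes
FRONT_EMPTY = 0b00
FRONT_FOOD = 0b01
FRONT_AGENT = 0b10
FRONT_WALL = 0b11


@dataclass(frozen=True)
class ObservationGA:
    """Seven sensor bits: 2 front-tile bits, 3 beep bits, 2 food bits."""

    front_code: int  # 0..3
    beep_bits: tuple[bool, bool, bool]  # other agents, ascending index
    food_bits: int  # min(food_held, 3)

    def bits(self) -> tuple[int, ...]:
        """Flatten to the 7 sensor bits, most significant bit first within
        each field: (front_hi, front_lo, beep0, beep1, beep2, food_hi, food_lo)."""
        return (
            (self.front_code >> 1) & 1,
            self.front_code & 1,
            int(self.beep_bits[0]),
            int(self.beep_bits[1]),
            int(self.beep_bits[2]),
            (self.food_bits >> 1) & 1,
            self.food_bits & 1,
        )


@dataclass(frozen=True)
class StateQ:
    """Fully observed state: one value per tile in row-major order.

    0 = empty, 1 = food, -1 = another agent, -0.5 = the agent under control
    (decentralized perspective only).  ``key`` is a compact hashable form
    used to index the sparse Q table; for the centralized perspective the
    ordered agent positions are appended so that permuted agent
    configurations never alias.
    """

    cells: tuple[float, ...]
    key: bytes


def _corners(side: int) -> list[tuple[int, int]]:
    return [(0, 0), (0, side - 1), (side - 1, 0), (side - 1, side - 1)]


class _World:
    """Shared machinery of both dialects (mutable; stepped in place)."""

    side: int
    max_time: int

    def __init__(self, grid, rows, cols, food, time=0, max_time=None):
        self.grid = np.asarray(grid, dtype=np.int8)
        self.side = self.grid.shape[0]
        self.rows = list(rows)
        self.cols = list(cols)
        self.food = list(food)
        self.time = time
        if max_time is not None:
            self.max_time = max_time

    @property
    def n_agents(self) -> int:
        return len(self.rows)

    def copy(self):
        return _copy.deepcopy(self)

    def occupant(self, r: int, c: int, skip: int = -1) -> int:
        """Index of the agent on tile (r, c), or -1."""
        for j in range(self.n_agents):
            if j != skip and self.rows[j] == r and self.cols[j] == c:
                return j
        return -1

    def in_bounds(self, r: int, c: int) -> bool:
        return 0 <= r < self.side and 0 <= c < self.side

    def to_dict(self) -> dict:
        d = {
            "grid": self.grid.tolist(),
            "agents": [
                {"row": self.rows[i], "col": self.cols[i], "food": self.food[i]}
                for i in range(self.n_agents)
            ],
            "time": self.time,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


class GAWorld(_World):
    """16x16 partially observed world with headings and beeps."""

    max_time = GA_EPISODE_LENGTH

    def __init__(self, grid, rows, cols, food, headings, beeping=None, time=0,
                 max_time=None):
        super().__init__(grid, rows, cols, food, time, max_time)
        self.headings = [Heading(h) for h in headings]
        self.beeping = list(beeping) if beeping is not None else [False] * self.n_agents

    def to_dict(self) -> dict:
        d = super().to_dict()
        for i, a in enumerate(d["agents"]):
            a["heading"] = self.headings[i].name
            a["beeping"] = bool(self.beeping[i])
        return d

    def step(self, actions: Sequence[ActionGA]) -> None:
        """Resolve one simultaneous update in place (sequential in agent index)."""
        if self.time >= self.max_time:
            raise ValueError(f"episode finished at time {self.time}")
        if len(actions) != self.n_agents:
            raise ValueError("one action per agent required")
        for i, act in enumerate(actions):
            mv = act.move
            if mv == MoveGA.NOTHING:
                continue
            if mv == MoveGA.LEFT:
                self.headings[i] = Heading((self.headings[i] - 1) % 4)
            elif mv == MoveGA.RIGHT:
                self.headings[i] = Heading((self.headings[i] + 1) % 4)
            else:  # FORWARD: move / eat / give food
                dr, dc = _DELTA[self.headings[i]]
                r, c = self.rows[i] + dr, self.cols[i] + dc
                if not self.in_bounds(r, c):
                    continue  # wall bump is a silent no-op
                j = self.occupant(r, c, skip=i)
                if j >= 0:
                    if self.food[i] > 0:  # give one token to the occupant
                        self.food[i] -= 1
                        self.food[j] += 1
                    continue  # mover stays put either way
                if self.grid[r, c] == 1:
                    self.grid[r, c] = 0
                    self.food[i] += 1
                self.rows[i], self.cols[i] = r, c
        self.beeping = [bool(a.beep) for a in actions]
        self.time += 1


class QWorld(_World):
    """8x8 fully observed world (headings unused); supports other sizes and
    agent counts for reduced single-agent setups."""

    max_time = Q_EPISODE_LENGTH

    def step(self, moves: Sequence[ActionQ]) -> list[int]:
        """Resolve one update in place; returns per-agent food deltas."""
        if self.time >= self.max_time:
            raise ValueError(f"episode finished at time {self.time}")
        if len(moves) != self.n_agents:
            raise ValueError("one move per agent required")
        delta = [0] * self.n_agents
        for i, mv in enumerate(moves):
            dr, dc = _DELTA_Q[ActionQ(mv)]
            r, c = self.rows[i] + dr, self.cols[i] + dc
            if not self.in_bounds(r, c):
                continue
            j = self.occupant(r, c, skip=i)
            if j >= 0:
                if self.food[i] > 0:
                    self.food[i] -= 1
                    self.food[j] += 1
                    delta[i] -= 1
                    delta[j] += 1
                continue
            if self.grid[r, c] == 1:
                self.grid[r, c] = 0
                self.food[i] += 1
                delta[i] += 1
            self.rows[i], self.cols[i] = r, c
        self.time += 1
        return delta


def build_world(dialect: str, seed: int, food_density: float = 1.0):
    """Build a fresh world with agents in the corners and zero inventories.

    Every non-corner tile independently holds food with probability
    ``food_density`` (default 1.0: a food-saturated room).  The same seed
    always yields the same world.

    Parameters
    ----------
    dialect : {"GA", "Q"}
    seed : int
        Seed for the food layout (only consulted when ``food_density`` < 1).
    food_density : float in (0, 1]
    """
    if not 0 < food_density <= 1:
        raise ValueError("food_density must be in (0, 1]")
    dialect = dialect.upper()
    if dialect not in ("GA", "Q"):
        raise ValueError(f"unknown dialect {dialect!r}")
    side = GA_SIDE if dialect == "GA" else Q_SIDE
    rng = np.random.default_rng(seed)
    grid = (rng.random((side, side)) < food_density).astype(np.int8)
    corners = _corners(side)
    for r, c in corners:
        grid[r, c] = 0
    rows = [r for r, _ in corners]
    cols = [c for _, c in corners]
    if dialect == "GA":
        # all agents start facing North: a deliberate symmetry break so that
        # the same controller behaves differently in different corners
        return GAWorld(grid, rows, cols, [0] * 4, [Heading.N] * 4)
    return QWorld(grid, rows, cols, [0] * 4)


def total_food(world: _World) -> int:
    """Tokens on the grid plus tokens held — conserved by every step."""
    return int(world.grid.sum()) + sum(world.food)


def observe_ga(world: GAWorld, agent_id: int) -> ObservationGA:
    """Egocentric seven-bit observation of one agent.

    The front code classifies the tile one step ahead of the heading
    (00 empty, 01 food, 10 agent, 11 wall); beep bits are the other agents'
    beep flags from the previous update; food bits saturate at 3.
    """
    if not 0 <= agent_id < world.n_agents:
        raise ValueError("invalid agent_id")
    dr, dc = _DELTA[world.headings[agent_id]]
    r, c = world.rows[agent_id] + dr, world.cols[agent_id] + dc
    if not world.in_bounds(r, c):
        code = FRONT_WALL
    elif world.occupant(r, c, skip=agent_id) >= 0:
        code = FRONT_AGENT
    elif world.grid[r, c] == 1:
        code = FRONT_FOOD
    else:
        code = FRONT_EMPTY
    beeps = tuple(bool(world.beeping[j]) for j in range(world.n_agents) if j != agent_id)
    return ObservationGA(code, beeps, min(world.food[agent_id], 3))


def step_ga(world: GAWorld, actions: Sequence[ActionGA]) -> GAWorld:
    """Pure variant of :meth:`GAWorld.step`: returns the stepped copy."""
    out = world.copy()
    out.step(actions)
    return out


def step_q(world: QWorld, moves: Sequence[ActionQ]) -> tuple[QWorld, list[int]]:
    """Pure variant of :meth:`QWorld.step`: returns (stepped copy, deltas)."""
    out = world.copy()
    delta = out.step(moves)
    return out, delta


def encode_state_q(world: QWorld, perspective) -> StateQ:
    """Encode the full grid as the Q-learning state.

    Decentralized (``perspective`` is an agent index): the controlled agent
    is -0.5, the others -1, food 1, empty 0.  Centralized
    (``perspective=CENTRALIZED``): every agent is -1 and the ordered list of
    agent positions is appended to the key, so two worlds that differ only
    by which agent sits where never collide.
    """
    side = world.side
    codes = bytearray(bytes(world.grid.reshape(-1).clip(0, 1)))  # 0 empty, 1 food
    if perspective == CENTRALIZED:
        for j in range(world.n_agents):
            codes[world.rows[j] * side + world.cols[j]] = 2
        key = bytes(codes) + bytes(
            b for j in range(world.n_agents) for b in (world.rows[j], world.cols[j])
        )
    else:
        if not 0 <= perspective < world.n_agents:
            raise ValueError("invalid perspective")
        for j in range(world.n_agents):
            codes[world.rows[j] * side + world.cols[j]] = 3 if j == perspective else 2
        key = bytes(codes)
    value = {0: 0.0, 1: 1.0, 2: -1.0, 3: -0.5}
    cells = tuple(value[b] for b in codes)
    return StateQ(cells, key)
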