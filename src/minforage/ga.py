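"""Generational genetic algorithm over Markov-Brain genomes.

Two group-formation regimes implement the two biological routes to
cooperation:

* ``GROUP_LS`` (group-level selection) — every genome is cloned three times
  and the four identical agents forage together; the group score credits
  the single parent genome.
* ``INCL_W`` (inclusive fitness) — groups of four *distinct* genomes are
  drawn by shuffled partition of the population; every member's fitness
  accumulates its group's score, and the partitioning is repeated several
  times per generation so each member is evaluated repeatedly in different
  company.

Selection is pure fitness-proportional (roulette wheel) with mutation and
no elitism or crossover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import markov_brain as mb
from .env import GAWorld, build_world, observe_ga
from .rewards import Scheme, aggregate

__all__ = [
    "Regime",
    "GAConfig",
    "run_episode",
    "evaluate_clonal",
    "evaluate_mixed",
    "roulette_select",
    "evolve",
    "GAResult",
]

GROUP_LS = "group_ls"
INCL_W = "incl_w"
Regime = str  # {"group_ls", "incl_w"}


@dataclass(frozen=True)
class GAConfig:
    regime: str = GROUP_LS
    scheme: Scheme = Scheme.MINIMUM
    population_size: int = 100
    generations: int = 100
    evaluations_per_gen: int = 4  # INCL_W only
    episode_length: int = 100
    genome_length: int = 5000
    max_gates: int | None = None
    rates: mb.MutationRates = field(default_factory=mb.MutationRates)
    food_density: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.regime not in (GROUP_LS, INCL_W):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.population_size < 4:
            raise ValueError("population must hold at least one group of 4")
        object.__setattr__(self, "scheme", Scheme.coerce(self.scheme))


def run_episode(
    gate_lists,
    world: GAWorld,
    rng: np.random.Generator,
    episode_length: int = 100,
) -> list[int]:
    """Run one foraging episode and return the per-agent food vector.

    ``gate_lists`` holds one decoded gate list per agent (clones share the
    same list object).  Each agent keeps its own recurrent brain state.
    The world is stepped in place.
    """
    n = world.n_agents
    states = [mb.new_brain_state() for _ in range(n)]
    world.max_time = episode_length
    for _ in range(episode_length):
        actions = []
        for i in range(n):
            mb.set_sensors(states[i], observe_ga(world, i).bits())
            states[i] = mb.brain_update(states[i], gate_lists[i], rng)
            actions.append(mb.actuate(states[i]))
        world.step(actions)
    return list(world.food)


def _fresh_world(config: GAConfig, world_seed: int) -> GAWorld:
    return build_world("GA", world_seed, config.food_density)


def evaluate_clonal(
    genome,
    world_seed: int,
    scheme,
    rng: np.random.Generator | None = None,
    config: GAConfig | None = None,
) -> tuple[float, list[int]]:
    """Score one genome by cloning it into a group of four identical agents.

    Returns ``(W, food_vector)`` where ``W`` is the scheme-aggregated group
    score credited to the single parent genome.
    """
    config = config or GAConfig(scheme=scheme)
    rng = rng if rng is not None else np.random.default_rng(world_seed)
    gates = mb.decode(genome, config.max_gates)
    world = _fresh_world(config, world_seed)
    food = run_episode([gates] * 4, world, rng, config.episode_length)
    return aggregate(food, scheme), food


def evaluate_mixed(
    genomes: list,
    rng: np.random.Generator,
    scheme,
    config: GAConfig | None = None,
    world_seed: int = 0,
) -> tuple[np.ndarray, list[tuple[tuple[int, ...], list[int]]]]:
    """Inclusive-fitness evaluation by repeated shuffled partition.

    The population is shuffled and split into groups of four distinct
    members; each member's fitness accumulates its group's scheme score.
    Repeated ``evaluations_per_gen`` times, so with N divisible by 4 every
    member appears in exactly that many groups.  Returns the fitness vector
    and the list of ``(member_indices, food_vector)`` per group evaluated.
    """
    config = config or GAConfig(scheme=scheme)
    n = len(genomes)
    if n < 4:
        raise ValueError("need at least 4 genomes")
    fitness = np.zeros(n)
    groups: list[tuple[tuple[int, ...], list[int]]] = []
    decoded = [mb.decode(g, config.max_gates) for g in genomes]
    ws = world_seed
    for _ in range(config.evaluations_per_gen):
        order = rng.permutation(n)
        for start in range(0, n - n % 4, 4):
            idx = tuple(int(i) for i in order[start : start + 4])
            world = _fresh_world(config, ws)
            ws += 1
            food = run_episode([decoded[i] for i in idx], world, rng, config.episode_length)
            w = aggregate(food, scheme)
            for i in idx:
                fitness[i] += w
            groups.append((idx, food))
    return fitness, groups


def roulette_select(
    genomes: list, fitness: np.ndarray, rates: mb.MutationRates, rng: np.random.Generator
) -> list:
    """Fitness-proportional offspring, each passed through mutation.

    A population with zero total fitness reproduces uniformly at random.
    """
    fitness = np.asarray(fitness, dtype=float)
    if fitness.shape != (len(genomes),):
        raise ValueError("one fitness per genome required")
    total = fitness.sum()
    p = fitness / total if total > 0 else None
    parents = rng.choice(len(genomes), size=len(genomes), replace=True, p=p)
    return [mb.mutate(genomes[int(i)], rates, rng) for i in parents]


@dataclass
class GAResult:
    """Per-generation trajectory and final per-agent food distributions."""

    config: GAConfig
    trajectory: list[dict]  # {generation, mean_group_food, best_group_food}
    final_food: list[int]  # best group's per-agent food vector, final generation
    final_population_food: list[list[int]]  # all evaluated groups' food vectors
    genomes: list  # final-generation population


def evolve(config: GAConfig) -> GAResult:
    """Run one replicate of the GA and log the group-food trajectory.

    "Group food" is the total food collected by a group (the sum of the
    four members' hauls); the per-generation log records its mean over all
    groups evaluated that generation and the best group's value.  The final
    distribution is the best-scoring group's per-agent food vector in the
    last evaluated generation.
    """
    rng = np.random.default_rng(config.seed)
    genomes = [mb.random_genome(config.genome_length, rng) for _ in range(config.population_size)]
    trajectory: list[dict] = []
    final_food: list[int] = [0, 0, 0, 0]
    final_groups: list[list[int]] = []
    world_seed = int(rng.integers(0, 2**31))

    for gen in range(config.generations + 1):  # +1: generation 0 is evaluated too
        if config.regime == GROUP_LS:
            fitness = np.zeros(config.population_size)
            foods = []
            for i, genome in enumerate(genomes):
                w, food = evaluate_clonal(genome, world_seed + gen, config.scheme, rng, config)
                fitness[i] = w
                foods.append(food)
            scores = fitness
        else:
            fitness, groups = evaluate_mixed(
                genomes, rng, config.scheme, config, world_seed + gen * 1000
            )
            foods = [food for _, food in groups]
            scores = np.array([aggregate(f, config.scheme) for f in foods])
        totals = np.array([sum(f) for f in foods])
        best = int(np.argmax(scores))
        trajectory.append(
            {
                "generation": gen,
                "mean_group_food": float(totals.mean()),
                "best_group_food": float(totals[best]),
            }
        )
        final_food = foods[best]
        final_groups = foods
        if gen == config.generations:
            break
        genomes = roulette_select(genomes, fitness, config.rates, rng)

    return GAResult(config, trajectory, final_food, final_groups, genomes)
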