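"""Group reward aggregation and the despotic-index fairness statistic.

A group of four foragers ends an episode with a food vector
``F = (F_0, F_1, F_2, F_3)``.  The group score ``W`` assigned uniformly to
all members is one of

* ``MEAN``    — ``W = (1/4) * sum_i F_i``  (pooled and split fairly),
* ``MINIMUM`` — ``W = min_i F_i``          (the weakest member's haul),
* ``MAXIMUM`` — ``W = max_i F_i``          (the strongest member's haul;
  a control that rewards monopolisation).

The same operators double as per-step reward shaping for reinforcement
learning, applied to the per-step food *deltas* rather than the cumulative
totals.

Fairness is summarised by the despotic index: within each replicate the
four end-of-episode hauls are sorted in descending order, averaged per rank
across replicates, and the least-squares slope of that ranked profile
against rank 0..3 is reported.  A slope of 0 means a perfectly even split;
a steeply negative slope means one agent monopolises the food.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Scheme", "DespoticProfile", "aggregate", "step_reward", "despotic_index"]

GROUP_SIZE = 4


class Scheme(str, Enum):
    MEAN = "mean"
    MINIMUM = "minimum"
    MAXIMUM = "maximum"

    @classmethod
    def coerce(cls, value) -> "Scheme":
        if isinstance(value, Scheme):
            return value
        return cls(str(value).lower())


def aggregate(food: Sequence[float], scheme, n_agents: int = GROUP_SIZE) -> float:
    """Collapse a per-agent food vector to the single group score ``W``.

    Rejects vectors whose length differs from ``n_agents`` (default: the
    four-member groups used throughout).
    """
    scheme = Scheme.coerce(scheme)
    f = np.asarray(food, dtype=float)
    if f.ndim != 1 or f.size != n_agents:
        raise ValueError(f"expected a length-{n_agents} food vector, got shape {f.shape}")
    if scheme is Scheme.MEAN:
        return float(f.mean())
    if scheme is Scheme.MINIMUM:
        return float(f.min())
    return float(f.max())


def step_reward(delta: Sequence[float], scheme) -> float:
    """Per-step shaped reward: the scheme applied to the step's food deltas.

    Deltas may be negative (a mover handing a token to an occupant), so no
    sign restriction applies here.  Summing the MEAN per-step rewards over
    an episode recovers the MEAN score of the final totals; for MINIMUM and
    MAXIMUM the per-step aggregate is a shaping signal, not the episode
    score.
    """
    return aggregate(delta, scheme, n_agents=len(delta))


@dataclass(frozen=True)
class DespoticProfile:
    """Rank-sorted mean food per rank and its least-squares slope."""

    ranked_means: tuple[float, ...]  # descending over rank 0..3
    slope: float  # food tokens per rank; <= 0 under the descending sort

    @property
    def rank1_share(self) -> float:
        """Fraction of the group's food held by the top-ranked agent."""
        tot = sum(self.ranked_means)
        return self.ranked_means[0] / tot if tot > 0 else 1.0 / len(self.ranked_means)


def despotic_index(per_agent_food: Iterable[Sequence[float]]) -> DespoticProfile:
    """Despotic profile over replicates of per-agent food vectors.

    Each replicate's vector is sorted in descending order; ranks are then
    averaged across replicates and a least-squares line is fit against rank
    index 0..k-1.  The slope is the despotic index: 0 for a perfectly flat
    (fair) distribution, increasingly negative as the distribution steepens.
    """
    arr = np.asarray(list(per_agent_food), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one replicate is required")
    if arr.ndim == 1:
        arr = arr[None, :]
    ranked = -np.sort(-arr, axis=1)  # descending within each replicate
    means = ranked.mean(axis=0)
    ranks = np.arange(means.size, dtype=float)
    slope = float(np.polyfit(ranks, means, 1)[0]) if means.size > 1 else 0.0
    # a constant profile is exactly flat; polyfit noise would obscure that
    if np.allclose(means, means[0]):
        slope = 0.0
    return DespoticProfile(tuple(float(m) for m in means), slope)
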