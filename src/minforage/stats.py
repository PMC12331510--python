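"""Replicate statistics: KS comparisons, Bonferroni, bootstrap CIs.

Experimental conditions are compared by the two-sample Kolmogorov-Smirnov
test — a non-parametric comparison of the full distributions of
per-replicate group scores, robust to the non-Gaussian, often multimodal
outcomes the simulations produce — with a Bonferroni-adjusted significance
threshold of 0.01/m over the m pairwise tests.  Ranked food profiles carry
95% percentile-bootstrap confidence intervals across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestReport",
    "ks_two_sample",
    "bonferroni_threshold",
    "ranked_ci",
    "pairwise_ks",
]


@dataclass(frozen=True)
class TestReport:
    """One pairwise KS comparison with its corrected significance flag."""

    condition_a: str
    condition_b: str
    D: float
    p: float
    threshold: float
    significant: bool


def ks_two_sample(x: Sequence[float], y: Sequence[float], exact: bool = False) -> tuple[float, float]:
    """Two-sample KS statistic and p-value.

    ``D`` is the supremum gap between the two empirical CDFs.  The p-value
    comes from the asymptotic Kolmogorov distribution by default; with
    ``exact=True`` the exact null distribution is used (sensible only for
    small samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = sps.ks_2samp(x, y, method="exact" if exact else "asymp")
    return float(res.statistic), float(res.pvalue)


def bonferroni_threshold(alpha0: float = 0.01, m: int = 1) -> float:
    """Family-wise significance threshold alpha0 / m for m comparisons."""
    if m < 1:
        raise ValueError("m must be at least 1")
    return alpha0 / m


def ranked_ci(
    result_table: Sequence[Sequence[float]],
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict:
    """Per-rank mean and percentile-bootstrap CI across replicates.

    ``result_table`` is (n_replicates, n_ranks) of rank-sorted per-agent
    food.  Returns ``{"mean", "lo", "hi"}`` arrays of length n_ranks.
    A level of 0 collapses the interval to the mean.
    """
    arr = np.asarray(result_table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("expected a (replicates, ranks) table")
    mean = arr.mean(axis=0)
    if level <= 0 or arr.shape[0] < 2:
        return {"mean": mean, "lo": mean.copy(), "hi": mean.copy()}
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.shape[0], size=(n_boot, arr.shape[0]))
    boot_means = arr[idx].mean(axis=1)  # (n_boot, n_ranks)
    tail = (1 - level) / 2 * 100
    lo = np.percentile(boot_means, tail, axis=0)
    hi = np.percentile(boot_means, 100 - tail, axis=0)
    return {"mean": mean, "lo": lo, "hi": hi}


def pairwise_ks(
    samples: dict[str, Sequence[float]],
    baselines: Sequence[str],
    alpha0: float = 0.01,
    exact: bool = False,
) -> list[TestReport]:
    """Every condition tested against every baseline (self-pairs excluded).

    With the canonical six conditions and two baselines this yields
    m = 6*2 - 2 = 10 tests; the threshold is Bonferroni-corrected to
    alpha0/m.
    """
    for b in baselines:
        if b not in samples:
            raise ValueError(f"baseline {b!r} has no sample")
    pairs = [
        (name, b) for b in baselines for name in samples if name != b
    ]
    m = len(pairs)
    thr = bonferroni_threshold(alpha0, m) if m else alpha0
    reports = []
    for name, b in pairs:
        d, p = ks_two_sample(samples[name], samples[b], exact=exact)
        reports.append(TestReport(name, b, d, p, thr, p < thr))
    return reports
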