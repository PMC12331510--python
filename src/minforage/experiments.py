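"""Experiment orchestration: seeds, replicates, persistence, comparisons.

A condition is an (engine, regime, scheme) triple named the way the result
figures label them — ``GroupLS-MINIMUM`` for group-level selection (clonal
groups, or the centralized policy in reinforcement learning) under the
weakest-member scheme, ``InclW-MEAN`` for inclusive fitness (random
groups / decentralized policies) under the mean scheme, and so on.

Two problem scales are built in: ``full`` runs the full-size experiments
(GA: population 100 over 50,000 generations; Q-learning: 10,000 epochs;
40 replicates) and ``desk`` runs the same condition grid at a reduced size
chosen so the qualitative ordering of conditions emerges on a single CPU
in minutes.  Every replicate draws its seed deterministically from the
master seed, so reruns of the same spec reproduce their output files
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ga import GAConfig, GROUP_LS, INCL_W, evolve
from .markov_brain import MutationRates
from .qlearning import QLConfig, train
from .rewards import Scheme, despotic_index
from .stats import pairwise_ks, ranked_ci

__all__ = [
    "ExperimentSpec",
    "SCHEMES",
    "REGIMES",
    "condition_name",
    "replicate_seed",
    "run_experiment",
    "run_condition",
    "load_condition_scores",
    "load_condition_finals",
    "compare_conditions",
    "despotic_table",
    "BASELINES",
]

SCHEMES = (Scheme.MEAN, Scheme.MINIMUM, Scheme.MAXIMUM)
REGIMES = (GROUP_LS, INCL_W)  # clonal/centralized vs random/decentralized
BASELINES = ("GroupLS-MEAN", "GroupLS-MINIMUM")

_REGIME_LABEL = {GROUP_LS: "GroupLS", INCL_W: "InclW"}

# desk-scale sizes: small enough for a single CPU, large enough for the
# condition ordering to be visible (see docs/methods.md)
DESK_GA = dict(
    population_size=20,
    generations=60,
    genome_length=400,
    max_gates=12,
    rates=MutationRates(
        p_point=0.005, p_delete=0.02, p_duplicate=0.05,
        segment_range=(8, 64), length_bounds=(100, 1200),
    ),
)
# the epsilon schedule is compressed so that 400 desk epochs traverse the
# same exploration->exploitation profile as 10,000 full-scale epochs at
# the canonical 0.999 per-epoch decay
DESK_QL = dict(epochs=400, batch=500, epsilon_decay=0.999 ** (10_000 / 400))
DESK_REPLICATES = 10

FULL_GA = dict(population_size=100, generations=50_000, genome_length=5000)
FULL_QL = dict(epochs=10_000, batch=2_000)
FULL_REPLICATES = 40


def condition_name(regime: str, scheme) -> str:
    return f"{_REGIME_LABEL[regime]}-{Scheme.coerce(scheme).name}"


@dataclass(frozen=True)
class ExperimentSpec:
    """Everything needed to reproduce one condition's replicates."""

    engine: str  # "ga" or "ql"
    regime: str = GROUP_LS  # group_ls (clonal/centralized) or incl_w
    scheme: Scheme = Scheme.MINIMUM
    scale: str = "desk"  # "desk" or "full"
    replicates: int | None = None
    master_seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.engine not in ("ga", "ql"):
            raise ValueError("engine is 'ga' or 'ql'")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.scale not in ("desk", "full"):
            raise ValueError("scale is 'desk' or 'full'")
        object.__setattr__(self, "scheme", Scheme.coerce(self.scheme))
        if self.replicates is None:
            object.__setattr__(
                self,
                "replicates",
                DESK_REPLICATES if self.scale == "desk" else FULL_REPLICATES,
            )

    @property
    def name(self) -> str:
        return condition_name(self.regime, self.scheme)

    def config(self, seed: int):
        """Engine config for one replicate with the given seed."""
        if self.engine == "ga":
            base = dict(DESK_GA if self.scale == "desk" else FULL_GA)
            base.update(self.overrides)
            return GAConfig(regime=self.regime, scheme=self.scheme, seed=seed, **base)
        base = dict(DESK_QL if self.scale == "desk" else FULL_QL)
        base.update(self.overrides)
        control = "centralized" if self.regime == GROUP_LS else "decentralized"
        return QLConfig(control=control, scheme=self.scheme, seed=seed, **base)


def replicate_seed(master_seed: int, replicate: int) -> int:
    """Disjoint per-replicate seed derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, replicate]).generate_state(1)[0] % 2**31)


def run_condition(spec: ExperimentSpec) -> list:
    """Run all replicates of one condition in memory; returns the result
    objects (GAResult or QLResult), one per replicate."""
    results = []
    for rep in range(spec.replicates):
        cfg = spec.config(replicate_seed(spec.master_seed, rep))
        results.append(evolve(cfg) if spec.engine == "ga" else train(cfg))
    return results


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def run_experiment(spec: ExperimentSpec, output_dir) -> Path:
    """Run one condition and persist trajectories, final distributions and
    a manifest under ``output_dir/<condition>/``.

    Per replicate: ``rep<i>_trajectory.csv`` (one row per generation/epoch)
    and ``rep<i>_final.csv`` (per-agent end-of-run food).  Condition-level:
    ``ranked_profile.csv`` (rank, mean food, bootstrap 95% CI) and
    ``manifest.json`` with the full configuration and all seeds.  Reruns
    with the same spec reproduce every file byte for byte.
    """
    out = Path(output_dir) / spec.name
    out.mkdir(parents=True, exist_ok=True)
    seeds = [replicate_seed(spec.master_seed, r) for r in range(spec.replicates)]
    finals = []
    for rep, seed in enumerate(seeds):
        cfg = spec.config(seed)
        res = evolve(cfg) if spec.engine == "ga" else train(cfg)
        traj = pd.DataFrame(res.trajectory)
        traj.insert(0, "replicate", rep)
        _write_csv(traj, out / f"rep{rep}_trajectory.csv")
        food = res.final_food
        fin = pd.DataFrame({"agent": range(len(food)), "food": food})
        fin.insert(0, "replicate", rep)
        _write_csv(fin, out / f"rep{rep}_final.csv")
        finals.append(food)
    ranked = -np.sort(-np.asarray(finals, dtype=float), axis=1)
    ci = ranked_ci(ranked, seed=spec.master_seed)
    prof = pd.DataFrame(
        {
            "agent_rank": range(ranked.shape[1]),
            "mean_food": ci["mean"],
            "ci_low": ci["lo"],
            "ci_high": ci["hi"],
        }
    )
    _write_csv(prof, out / "ranked_profile.csv")
    manifest = {
        "version": __version__,
        "spec": {
            **{k: v for k, v in dataclasses.asdict(spec).items() if k != "scheme"},
            "scheme": spec.scheme.name,
        },
        "condition": spec.name,
        "replicate_seeds": seeds,
        "files": sorted(p.name for p in out.iterdir() if p.suffix == ".csv"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def load_condition_finals(condition_dir) -> np.ndarray:
    """(replicates, agents) final food table from a condition directory."""
    d = Path(condition_dir)
    reps = sorted(d.glob("rep*_final.csv"), key=lambda p: int(p.stem.split("_")[0][3:]))
    if not reps:
        raise FileNotFoundError(f"no final-distribution files under {d}")
    return np.array([pd.read_csv(p)["food"].to_numpy() for p in reps], dtype=float)


def load_condition_scores(condition_dir) -> np.ndarray:
    """Per-replicate group food (sum over agents) for KS comparisons."""
    return load_condition_finals(condition_dir).sum(axis=1)


def compare_conditions(result_dirs: dict, baselines=BASELINES, alpha0: float = 0.01) -> pd.DataFrame:
    """KS-compare every condition against the two baselines.

    ``result_dirs`` maps condition name to its result directory (or
    directly to a 1-D array of per-replicate scores).  Returns the test
    report table with Bonferroni-adjusted significance flags.
    """
    samples = {}
    for name, src in result_dirs.items():
        if isinstance(src, (str, Path)):
            samples[name] = load_condition_scores(src)
        else:
            samples[name] = np.asarray(src, dtype=float)
    missing = [b for b in baselines if b not in samples]
    if missing:
        raise ValueError(f"missing baseline condition(s): {missing}")
    reports = pairwise_ks(samples, baselines, alpha0=alpha0)
    return pd.DataFrame(
        [
            {
                "condition_a": r.condition_a,
                "condition_b": r.condition_b,
                "D": r.D,
                "p": r.p,
                "threshold": r.threshold,
                "significant": r.significant,
            }
            for r in reports
        ]
    )


def despotic_table(result_dirs: dict) -> pd.DataFrame:
    """Despotic profile (ranked means and slope) per condition."""
    rows = []
    for name, src in result_dirs.items():
        finals = load_condition_finals(src) if isinstance(src, (str, Path)) else np.asarray(src, float)
        prof = despotic_index(finals)
        rows.append(
            {
                "condition": name,
                "slope": prof.slope,
                "rank1_share": prof.rank1_share,
                **{f"rank{i}_mean": m for i, m in enumerate(prof.ranked_means)},
            }
        )
    return pd.DataFrame(rows)
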