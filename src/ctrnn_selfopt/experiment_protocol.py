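"""Three-stage experiment harness with replication and statistics.

One *repetition* on a given original weight matrix ``alpha``:

- **before-learning**: relax ``n_before`` random initial states on
  ``alpha`` with no learning;
- **learning**: the self-optimization loop for ``n_learning`` relaxations;
- **after-learning**: relax ``n_after`` random initial states on the
  learned weights with no learning.

Satisfied-constraint counts are always scored against the original
``alpha``.  Success is judged per repetition with a two-sided Welch
t-test comparing the before and after count samples — each repetition is
an individual experiment — and the reported statistic is the mean of the
per-repetition p-values across all weight configurations and repetitions,
alongside pooled stage means, percentages and count histograms.

Seeding is counter-based: every (configuration, repetition) cell derives
its generator from the master seed and its own indices, so any single
cell can be re-run in isolation and the full experiment is reproducible
bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ctrnn_core import NodeParams, RelaxationRecord, WeightMatrix, relax_batch
from .metrics_attractors import cluster_attractors, count_satisfied
from .self_optimization import (
    DEFAULT_STATE_BOUNDS,
    LearningConfig,
    run_self_optimization,
)
from .weight_conditions import ConditionSpec, generate

__all__ = [
    "ExperimentPlan",
    "ExperimentSummary",
    "run_repetition",
    "t_test_two_sample",
    "run_experiment",
]


@dataclass
class ExperimentPlan:
    """Replication structure of the full experiment.

    Full scale is 100 weight configurations x 100 repetitions with
    100 / 1,000 / 100 before / learning / after relaxations; desk-scale
    runs shrink the replication counts, never the per-repetition
    relaxation structure.
    """

    condition: ConditionSpec
    n_weight_configs: int = 100
    n_repetitions_per_config: int = 100
    n_before: int = 100
    n_learning: int = 1000
    n_after: int = 100
    master_seed: int = 0
    delta: float | None = None  # None -> condition family default
    state_bounds: tuple[float, float] = DEFAULT_STATE_BOUNDS
    mode: str = "asynchronous"
    dt: float = 0.1
    duration: float = 500.0
    tau_range: tuple[float, float] = (1.0, 10.0)
    gain_range: tuple[float, float] = (10.0, 20.0)

    def __post_init__(self) -> None:
        for name in ("n_weight_configs", "n_repetitions_per_config",
                     "n_before", "n_learning", "n_after"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")

    @property
    def effective_delta(self) -> float:
        return self.condition.default_learning_rate if self.delta is None else self.delta

    def learning_config(self) -> LearningConfig:
        return LearningConfig(
            delta=self.effective_delta,
            n_learning_relaxations=self.n_learning,
            state_bounds=self.state_bounds,
            mode=self.mode,
        )

    def rng_for(self, config_index: int, repetition_index: int,
                stream: int = 0) -> np.random.Generator:
        """Deterministic per-cell generator from the master seed."""
        ss = np.random.SeedSequence(
            entropy=self.master_seed,
            spawn_key=(config_index, repetition_index, stream),
        )
        return np.random.default_rng(ss)


@dataclass
class ExperimentSummary:
    """Aggregate statistics of one experiment run."""

    n_nodes: int
    condition_family: str
    before_mean_count: float
    after_mean_count: float
    before_mean_percent: float
    after_mean_percent: float
    improvement_percent: float
    p_values: np.ndarray          # one Welch p per (config, repetition)
    mean_p_value: float
    before_counts: np.ndarray     # pooled across configs and repetitions
    after_counts: np.ndarray
    histogram: pd.DataFrame = field(repr=False)
    #: per-repetition visit fraction of the dominant after-stage attractor,
    #: with conjugate (sign-flipped) endpoints identified
    after_dominance: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_nodes": self.n_nodes,
            "condition_family": self.condition_family,
            "before_mean_count": self.before_mean_count,
            "after_mean_count": self.after_mean_count,
            "before_mean_percent": self.before_mean_percent,
            "after_mean_percent": self.after_mean_percent,
            "improvement_percent": self.improvement_percent,
            "mean_p_value": self.mean_p_value,
            "p_values": self.p_values.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _stage_records(
    alpha: WeightMatrix,
    weights: WeightMatrix,
    params: NodeParams,
    n: int,
    bounds: tuple[float, float],
    mode: str,
    rng: np.random.Generator,
    stage: str,
) -> list[RelaxationRecord]:
    """Relax ``n`` random initial states with no learning; score vs alpha."""
    S0 = rng.uniform(bounds[0], bounds[1], size=(n, alpha.n_nodes))
    records = relax_batch(S0, weights, params, mode=mode, rng=rng)
    for rec in records:
        rec.satisfied_constraints = count_satisfied(alpha, rec.final_V)
        rec.stage = stage
    return records


def run_repetition(
    alpha: WeightMatrix,
    params: NodeParams,
    cfg: LearningConfig,
    rng: np.random.Generator,
    n_before: int = 100,
    n_after: int = 100,
) -> tuple[list[RelaxationRecord], list[RelaxationRecord], list[RelaxationRecord]]:
    """One before / learning / after repetition on a fresh copy of alpha.

    No learning occurs in the before and after stages; the after stage
    runs on the weights learned in this repetition only.
    """
    before = _stage_records(
        alpha, alpha.as_omega(), params, n_before, cfg.state_bounds, cfg.mode,
        rng, "before",
    )
    omega, learning = run_self_optimization(alpha, params, cfg, rng)
    after = _stage_records(
        alpha, omega, params, n_after, cfg.state_bounds, cfg.mode, rng, "after",
    )
    return before, learning, after


def t_test_two_sample(before_counts, after_counts) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value on raw counts.

    Degenerate case: both samples constant with equal means -> p = 1.
    """
    before = np.asarray(before_counts, dtype=np.float64)
    after = np.asarray(after_counts, dtype=np.float64)
    if before.size < 2 or after.size < 2:
        raise ValueError("both samples need at least two observations")
    if before.std() == 0.0 and after.std() == 0.0:
        return 1.0 if before.mean() == after.mean() else 0.0
    with warnings.catch_warnings():
        # nearly-constant samples (after-learning stages often are) trip a
        # catastrophic-cancellation warning inside the moment computation
        warnings.simplefilter("ignore", RuntimeWarning)
        p = float(stats.ttest_ind(before, after, equal_var=False).pvalue)
    if np.isnan(p):
        return 1.0 if before.mean() == after.mean() else 0.0
    return p


def records_to_frame(records: list[RelaxationRecord]) -> pd.DataFrame:
    """Per-relaxation trace as a tidy table (one row per relaxation)."""
    return pd.DataFrame(
        {
            "relaxation_index": np.arange(len(records)),
            "stage": [r.stage for r in records],
            "satisfied_constraints": [r.satisfied_constraints for r in records],
            "converged": [r.converged for r in records],
        }
    )


def run_experiment(plan: ExperimentPlan, progress: bool = False) -> ExperimentSummary:
    """Run the full replication grid and aggregate the statistics."""
    n_nodes = plan.condition.n_nodes
    cfg = plan.learning_config()
    p_values = []
    dominance = []
    before_all: list[np.ndarray] = []
    after_all: list[np.ndarray] = []
    for c in range(plan.n_weight_configs):
        alpha = generate(plan.condition, plan.rng_for(c, 0, stream=1))
        for r in range(plan.n_repetitions_per_config):
            rng = plan.rng_for(c, r)
            params = NodeParams.random(
                n_nodes, rng,
                tau_range=plan.tau_range, gain_range=plan.gain_range,
                weights=alpha, dt=plan.dt, duration=plan.duration,
            )
            before, _, after = run_repetition(
                alpha, params, cfg, rng,
                n_before=plan.n_before, n_after=plan.n_after,
            )
            b = np.array([x.satisfied_constraints for x in before])
            a = np.array([x.satisfied_constraints for x in after])
            p_values.append(t_test_two_sample(b, a))
            catalog = cluster_attractors(after, identify_sign_flip=True)
            dominance.append(float(catalog.basin_fractions.max()))
            before_all.append(b)
            after_all.append(a)
    before_counts = np.concatenate(before_all)
    after_counts = np.concatenate(after_all)
    n_sq = n_nodes**2
    hist = _stage_histogram(before_counts, after_counts, n_sq)
    return ExperimentSummary(
        n_nodes=n_nodes,
        condition_family=plan.condition.family,
        before_mean_count=float(before_counts.mean()),
        after_mean_count=float(after_counts.mean()),
        before_mean_percent=100.0 * float(before_counts.mean()) / n_sq,
        after_mean_percent=100.0 * float(after_counts.mean()) / n_sq,
        improvement_percent=100.0 * float(after_counts.mean() - before_counts.mean()) / n_sq,
        p_values=np.array(p_values),
        mean_p_value=float(np.mean(p_values)),
        before_counts=before_counts,
        after_counts=after_counts,
        histogram=hist,
        after_dominance=np.array(dominance),
    )


def _stage_histogram(before: np.ndarray, after: np.ndarray, n_sq: int) -> pd.DataFrame:
    """Relative-frequency histogram over integer counts, pooled per stage."""
    bins = np.arange(0, n_sq + 2)
    b_freq, _ = np.histogram(before, bins=bins)
    a_freq, _ = np.histogram(after, bins=bins)
    mask = (b_freq > 0) | (a_freq > 0)
    return pd.DataFrame(
        {
            "count": bins[:-1][mask],
            "before_frequency": b_freq[mask] / before.size,
            "after_frequency": a_freq[mask] / after.size,
        }
    )
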