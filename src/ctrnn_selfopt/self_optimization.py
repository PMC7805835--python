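"""Hebbian self-optimization of a CTRNN's attractor landscape.

The iterative loop:

1. randomize the node activations uniformly within sampling bounds;
2. relax the network for a fixed duration, ideally onto a fixed point;
3. reinforce the reached output configuration with one Hebbian increment
   ``w_ij += delta * V_i * V_j`` (all ordered pairs, self-connections
   included), clipping every weight to ``[-1, 1]``.

Repeated over many relaxations with a small learning rate, the network
forms an associative memory of its own visited attractors.  Because
low-lying attractors tend to have the larger basins, reinforcement
preferentially enlarges the basins of configurations that satisfy more of
the original constraints, until one attractor dominates the state space.
Reinforcement is applied only at the end of each relaxation: with
unconstrained parameters the transient can be long, and the endpoint is
the best available estimate of an attractor (or at least of a point well
inside its basin).

Scoring is always against the frozen original matrix ``alpha``; learning
modifies only the working copy ``omega``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ctrnn_core import (
    IntegrationError,
    NetworkState,
    NodeParams,
    RelaxationRecord,
    WeightMatrix,
    node_outputs,
    relax,
    relax_batch,
)
from .metrics_attractors import cluster_attractors, count_satisfied

__all__ = ["LearningConfig", "randomize_state", "hebbian_update", "run_self_optimization"]

#: Default activation-sampling box for step 1.  The box must be wide
#: enough that the initial output signs are not dictated by the bias
#: terms: biases scale with half the weight row sums, and (-10, 10)
#: comfortably dominates them at the default conditions, sampling all
#: basins while keeping the post-sigmoid outputs spread over the
#: hypercube corners.
DEFAULT_STATE_BOUNDS = (-10.0, 10.0)


@dataclass
class LearningConfig:
    """Learning-rate, run-length and sampling settings for the loop.

    ``delta`` defaults to 0.001 (symmetric weight conditions); use 0.0005
    for the asymmetric ones, where the same rate over-commits to early
    suboptimal attractors.  ``weight_clip`` bounds every learned weight.
    """

    delta: float = 0.001
    n_learning_relaxations: int = 1000
    state_bounds: tuple[float, float] = DEFAULT_STATE_BOUNDS
    weight_clip: tuple[float, float] = (-1.0, 1.0)
    mode: str = "asynchronous"

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.state_bounds[0] >= self.state_bounds[1]:
            raise ValueError("state_bounds lower bound must be below upper bound")
        if self.weight_clip[0] >= self.weight_clip[1]:
            raise ValueError("weight_clip lower bound must be below upper bound")
        if self.n_learning_relaxations < 0:
            raise ValueError("n_learning_relaxations must be non-negative")


def randomize_state(
    n_nodes: int,
    bounds: tuple[float, float],
    rng: np.random.Generator,
    params: NodeParams,
) -> NetworkState:
    """Step 1: each activation drawn independently from U[lower, upper]."""
    lower, upper = bounds
    if lower > upper:
        raise ValueError("lower bound exceeds upper bound")
    s = rng.uniform(lower, upper, size=n_nodes)
    return NetworkState(s=s, V=node_outputs(s, params))


def hebbian_update(W: WeightMatrix, V: np.ndarray, delta: float,
                   clip: tuple[float, float] = (-1.0, 1.0)) -> WeightMatrix:
    """Step 3: ``w_ij <- clip(w_ij + delta * V_i * V_j)`` for all ordered
    pairs including the diagonal.  The increment matrix is the symmetric
    outer product ``delta * V V^T``, so symmetric weights stay symmetric
    and asymmetry never grows under learning."""
    if W.role != "current_omega":
        raise ValueError("learning applies to the working omega copy, not the original alpha")
    V = np.asarray(V, dtype=np.float64)
    values = np.clip(W.values + delta * np.outer(V, V), clip[0], clip[1])
    return WeightMatrix(values, role="current_omega", seed=W.seed)


def _check_multistability(alpha, params, cfg, rng, n_probe=100, min_attractors=2):
    """The mechanism needs multiple initial attractors to select among
    (otherwise there is nothing to optimize); probe and warn if absent."""
    S0 = rng.uniform(*cfg.state_bounds, size=(n_probe, alpha.n_nodes))
    records = relax_batch(S0, alpha.as_omega(), params, mode=cfg.mode, rng=rng)
    catalog = cluster_attractors(records)
    if catalog.n_attractors < min_attractors:
        warnings.warn(
            f"initial dynamics show only {catalog.n_attractors} distinct "
            "attractor(s) across the probe sample; self-optimization has "
            "nothing to select among",
            stacklevel=3,
        )
    return catalog


def _check_learning_rate(cfg: LearningConfig, n_nodes: int) -> None:
    """A rate large enough to saturate a weight within ~10 relaxations
    collapses the landscape before enough attractors are sampled."""
    if cfg.delta * 10.0 >= (cfg.weight_clip[1] - cfg.weight_clip[0]) / 2.0:
        warnings.warn(
            f"learning rate delta={cfg.delta} can drive weights to the clip "
            "boundary within ~10 relaxations; the landscape will collapse "
            "before the attractor distribution is sampled",
            stacklevel=3,
        )


def run_self_optimization(
    alpha: WeightMatrix,
    params: NodeParams,
    cfg: LearningConfig,
    rng: np.random.Generator,
    diagnostics: bool = False,
) -> tuple[WeightMatrix, list[RelaxationRecord]]:
    """Run the randomize-relax-reinforce loop.

    Starts from a working copy ``omega = alpha`` and repeats
    ``cfg.n_learning_relaxations`` times: randomize the state, relax on the
    current ``omega``, reinforce the endpoint outputs.  Each record carries
    the satisfied-constraint count scored against the original ``alpha``.

    With ``diagnostics=True`` the initial landscape is probed for
    multistability and the learning rate sanity-checked (warnings, never
    errors).  Returns the learned weights and the per-relaxation trace.
    """
    if alpha.role != "original_alpha":
        raise ValueError("run_self_optimization expects the original alpha matrix")
    _check_learning_rate(cfg, alpha.n_nodes)
    if diagnostics:
        _check_multistability(alpha, params, cfg, rng)
    omega = alpha.as_omega()
    trace: list[RelaxationRecord] = []
    for k in range(cfg.n_learning_relaxations):
        state = randomize_state(alpha.n_nodes, cfg.state_bounds, rng, params)
        try:
            rec = relax(state, omega, params, mode=cfg.mode, rng=rng)
        except IntegrationError as err:
            raise IntegrationError(err.step) from RuntimeError(
                f"integration failed during learning relaxation {k}"
            )
        omega = hebbian_update(omega, rec.final_V, cfg.delta, cfg.weight_clip)
        rec.satisfied_constraints = count_satisfied(alpha, rec.final_V)
        rec.stage = "learning"
        trace.append(rec)
    return omega, trace
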