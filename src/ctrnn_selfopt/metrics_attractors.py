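"""Constraint scoring, attractor identification and basin-size estimation.

A constraint is an ordered node pair ``(i, j)`` — self-pairs included — and
it is *satisfied* by an output configuration ``V`` when
``alpha_ij * V_i * V_j > 0`` strictly, where ``alpha`` is the ORIGINAL
weight matrix that defines the problem.  Learning modifies a working copy
of the weights, never the scoring matrix, so scores before and after
learning are comparable.  With strict inequality, zero products (zero
weight or zero output) count as unsatisfied, and the all-zero state scores
zero.  An N-node network has N^2 constraints (900 at N=30).
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np

from .ctrnn_core import (
    NodeParams,
    RelaxationRecord,
    WeightMatrix,
    relax_batch,
)

__all__ = [
    "AttractorCatalog",
    "count_satisfied",
    "percent_satisfied",
    "cluster_attractors",
    "estimate_basins",
]

#: L-infinity tolerance under which two relaxation endpoints count as the
#: same attractor.  Outputs span (-1, 1) and high gains push fixed points
#: toward hypercube corners, so 0.05 separates corners cleanly.
ATTRACTOR_TOL = 0.05


def count_satisfied(alpha: WeightMatrix, V: np.ndarray) -> int:
    """Number of ordered pairs (i, j), diagonal included, with
    ``alpha_ij * V_i * V_j > 0``."""
    if alpha.role != "original_alpha":
        raise ValueError("constraints are scored against the original alpha matrix")
    V = np.asarray(V, dtype=np.float64)
    return int(np.count_nonzero(alpha.values * np.outer(V, V) > 0.0))


def percent_satisfied(alpha: WeightMatrix, V: np.ndarray) -> float:
    """Satisfied constraints as a percentage of the N^2 possible."""
    return 100.0 * count_satisfied(alpha, V) / alpha.n_nodes**2


@dataclass
class AttractorCatalog:
    """Distinct relaxation endpoints with visit counts and basin estimates.

    ``basin_fractions`` are the visit frequencies across the sampled
    initial states — a Monte-Carlo estimate of relative basin volume over
    the sampling box — with binomial standard errors.
    """

    representatives: list[np.ndarray]
    counts: np.ndarray
    tol: float = ATTRACTOR_TOL

    @property
    def n_attractors(self) -> int:
        return len(self.representatives)

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    @property
    def basin_fractions(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def basin_standard_errors(self) -> np.ndarray:
        p, n = self.basin_fractions, self.n_samples
        return np.sqrt(p * (1.0 - p) / n)

    def to_json(self, path: str | Path, seed: int | None = None) -> None:
        payload = {
            "tol": self.tol,
            "seed": seed,
            "counts": self.counts.tolist(),
            "basin_fractions": self.basin_fractions.tolist(),
            "representatives": [r.tolist() for r in self.representatives],
        }
        Path(path).write_text(json.dumps(payload))


def cluster_attractors(
    records: list[RelaxationRecord],
    tol: float = ATTRACTOR_TOL,
    identify_sign_flip: bool = False,
) -> AttractorCatalog:
    """Greedy L-infinity clustering of relaxation endpoints.

    Endpoints are assigned, in input order, to the first existing cluster
    whose representative (the cluster's first member) lies within ``tol``
    in max-norm of the endpoint; otherwise they found a new cluster.
    Deterministic given the input order.

    With ``identify_sign_flip=True`` an endpoint also joins a cluster when
    its global sign flip ``-V`` is within ``tol`` of the representative.
    The constraint score and the Hebbian increment are both invariant
    under ``V -> -V``, so fixed points come in conjugate pairs that are
    equivalent as solutions; the flag clusters on that quotient, which is
    the natural notion of attractor identity when asking whether one
    *solution* dominates the landscape.
    """
    if not records:
        raise ValueError("cannot cluster an empty record list")
    reps: list[np.ndarray] = []
    counts: list[int] = []
    for rec in records:
        for idx, rep in enumerate(reps):
            d = np.max(np.abs(rec.final_V - rep))
            if identify_sign_flip:
                d = min(d, np.max(np.abs(rec.final_V + rep)))
            if d <= tol:
                counts[idx] += 1
                break
        else:
            reps.append(np.asarray(rec.final_V, dtype=np.float64))
            counts.append(1)
    return AttractorCatalog(representatives=reps, counts=np.array(counts), tol=tol)


def estimate_basins(
    W: WeightMatrix,
    params: NodeParams,
    n_samples: int,
    bounds: tuple[float, float],
    rng: np.random.Generator,
    mode: str = "asynchronous",
    tol: float = ATTRACTOR_TOL,
    identify_sign_flip: bool = False,
) -> AttractorCatalog:
    """Monte-Carlo basin-size estimate: relax ``n_samples`` random initial
    states drawn uniformly from ``bounds`` and cluster the endpoints."""
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    lower, upper = bounds
    S0 = rng.uniform(lower, upper, size=(n_samples, W.n_nodes))
    records = relax_batch(S0, W, params, mode=mode, rng=rng)
    return cluster_attractors(records, tol=tol, identify_sign_flip=identify_sign_flip)
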