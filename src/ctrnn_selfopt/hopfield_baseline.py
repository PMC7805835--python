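"""Discrete-time discrete-state Hopfield self-optimization baseline.

The classical mechanism on which the CTRNN loop is modeled: binary states
``s_i in {-1, +1}`` updated asynchronously by

    s_i <- theta_HT( sum_j w_ij s_j ),

with the Heaviside threshold ``theta_HT(x) = +1 if x >= 0 else -1``, the
incremental Hebb rule ``w_ij += delta * s_i * s_j``, the Hopfield energy
``E = -(1/2) sum_ij w_ij s_i s_j`` and the *original* energy
``E0 = -sum_ij alpha_ij s_i s_j`` scored against the frozen initial
weights.  For symmetric weights with non-negative diagonal, asynchronous
updates never increase E, so every relaxation terminates at a fixed point;
this well-characterized model serves as the mechanism's oracle and a
regression anchor for the continuous-time implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "heaviside_threshold",
    "hopfield_async_sweep",
    "hopfield_energy",
    "original_energy",
    "relax_hopfield",
    "run_hopfield_selfopt",
]


def heaviside_threshold(x):
    """+1 for x >= 0, else -1 (ties resolve to +1)."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("threshold input must be finite")
    out = np.where(x >= 0.0, 1.0, -1.0)
    return out if out.ndim else float(out)


def hopfield_async_sweep(s: np.ndarray, W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One full asynchronous sweep: nodes updated in a fresh random order,
    each seeing the freshest states."""
    s = np.asarray(s, dtype=np.float64).copy()
    for i in rng.permutation(s.shape[0]):
        s[i] = heaviside_threshold(W[i] @ s)
    return s


def hopfield_energy(W: np.ndarray, s: np.ndarray) -> float:
    """E = -(1/2) sum_ij w_ij s_i s_j."""
    return -0.5 * float(s @ W @ s)


def original_energy(alpha: np.ndarray, s: np.ndarray) -> float:
    """E0 = -sum_ij alpha_ij s_i s_j, scored against the original weights."""
    return -float(s @ alpha @ s)


def relax_hopfield(
    s: np.ndarray,
    W: np.ndarray,
    rng: np.random.Generator,
    max_sweeps: int | None = None,
) -> tuple[np.ndarray, bool]:
    """Sweep until the state is unchanged over a full sweep (fixed point)
    or ``max_sweeps`` is exhausted.  Default budget N^2 sweeps."""
    n = s.shape[0]
    if max_sweeps is None:
        max_sweeps = n * n
    for _ in range(max_sweeps):
        s_new = hopfield_async_sweep(s, W, rng)
        if np.array_equal(s_new, s):
            return s_new, True
        s = s_new
    return s, False


@dataclass
class HopfieldTraceEntry:
    satisfied_constraints: int
    original_energy: float
    converged: bool
    final_s: np.ndarray


def count_satisfied_discrete(alpha: np.ndarray, s: np.ndarray) -> int:
    """Ordered pairs with alpha_ij * s_i * s_j > 0, diagonal included."""
    return int(np.count_nonzero(alpha * np.outer(s, s) > 0.0))


def run_hopfield_selfopt(
    alpha: np.ndarray,
    n_relaxations: int,
    delta: float,
    rng: np.random.Generator,
    sweeps_per_relaxation: int | None = None,
) -> tuple[np.ndarray, list[HopfieldTraceEntry]]:
    """The randomize-relax-reinforce loop on the discrete model.

    ``alpha`` must be symmetric with diagonal entries in {0, 1} (the
    classical setting, which guarantees convergence).  Relaxation runs to
    a detected fixed point by default.  Returns the learned weights and
    the per-relaxation trace of constraint counts and original energies.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    if not np.allclose(alpha, alpha.T):
        raise ValueError("the discrete baseline requires symmetric original weights")
    diag = np.diag(alpha)
    if not np.all(np.isin(diag, (0.0, 1.0))):
        raise ValueError("diagonal entries must be 0 or 1 in the discrete baseline")
    W = alpha.copy()
    n = alpha.shape[0]
    trace: list[HopfieldTraceEntry] = []
    for _ in range(n_relaxations):
        s0 = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        s, converged = relax_hopfield(s0, W, rng, max_sweeps=sweeps_per_relaxation)
        W = W + delta * np.outer(s, s)
        trace.append(
            HopfieldTraceEntry(
                satisfied_constraints=count_satisfied_discrete(alpha, s),
                original_energy=original_energy(alpha, s),
                converged=converged,
                final_s=s,
            )
        )
    return W, trace
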