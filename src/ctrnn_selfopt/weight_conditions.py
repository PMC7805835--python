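"""Seeded generators for the four initial-constraint weight conditions.

The initial weight matrix ``alpha`` defines a constraint-satisfaction
problem over node-output signs.  Four families are provided:

- **SR** (symmetric random): diagonal entries uniform on ``[-1, 1]``,
  off-diagonal entries uniform on ``[-0.1, 0.1]`` drawn once per unordered
  pair and mirrored.
- **AR** (asymmetric random): diagonal as SR; each ordered off-diagonal
  entry is ``q + u`` with ``|q| = 0.1``, the sign of ``q`` positive with
  probability 0.5, and ``u`` uniform on ``[-0.1, 0.1]``, all drawn
  independently per ordered pair.
- **SM** (symmetric modular): nodes partitioned into contiguous modules;
  entry magnitude 1 within a module (diagonal included) and 0.01 between
  modules; sign drawn once per unordered pair, positive with probability
  ``p_positive`` (default 0.8), mirrored.
- **AM** (asymmetric modular): a fresh SM draw with the diagonal kept and
  every ordered off-diagonal entry independently perturbed by a uniform
  value on ``[-0.01, 0.01]``.

Modular problems are the structured regime: strong within-module couplings
create semi-independent blocks separated by weak links, which is where
Hebbian self-optimization generalizes to unvisited, better attractors.
Modules are contiguous index blocks, ``module(i) = floor(i / module_size)``
with ``module_size = 3`` by default — ten three-node modules at N=30.
Three-node modules with mixed signs are individually frustrated, so the
initial landscape holds dozens of attractors composed of per-module
sub-solutions; much larger modules each collapse onto one internal
solution and leave the network effectively monostable, which removes the
attractor competition the mechanism feeds on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .ctrnn_core import WeightMatrix

__all__ = ["ConditionSpec", "generate", "generate_sr", "generate_ar",
           "generate_sm", "generate_am", "is_symmetric"]

Family = Literal["SR", "AR", "SM", "AM"]

#: Default nodes per module for the modular conditions: ten 3-node modules
#: at N=30.  Small frustrated modules keep the initial landscape
#: multistable, the regime the mechanism requires.
DEFAULT_MODULE_SIZE = 3


@dataclass
class ConditionSpec:
    """Parameters of one weight-condition family.

    ``module_size`` is the number of nodes per module (modular families;
    default 3).  ``q_magnitude`` is the |q| offset of the AR family and
    ``p_positive`` the probability that a modular entry's sign is
    positive.
    """

    family: Family
    n_nodes: int = 30
    module_size: int | None = None
    p_positive: float = 0.8
    q_magnitude: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in ("SR", "AR", "SM", "AM"):
            raise ValueError(f"unknown condition family {self.family!r}")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        if self.family in ("SM", "AM"):
            if self.module_size is None:
                self.module_size = DEFAULT_MODULE_SIZE
            if self.n_nodes % self.module_size:
                raise ValueError(
                    f"module_size={self.module_size} does not divide n_nodes={self.n_nodes}"
                )
        if not 0.0 <= self.p_positive <= 1.0:
            raise ValueError("p_positive must lie in [0, 1]")
        if self.q_magnitude <= 0:
            raise ValueError("q_magnitude must be positive")

    @property
    def is_symmetric_family(self) -> bool:
        return self.family in ("SR", "SM")

    @property
    def default_learning_rate(self) -> float:
        """delta = 0.001 for the symmetric families, 0.0005 for the asymmetric."""
        return 0.001 if self.is_symmetric_family else 0.0005


def _rng_for(spec: ConditionSpec, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    if spec.seed is None:
        raise ValueError("either pass an rng or set spec.seed")
    return np.random.default_rng(spec.seed)


def generate_sr(spec: ConditionSpec, rng: np.random.Generator | None = None) -> WeightMatrix:
    """Symmetric random: diag ~ U[-1,1], off-diag ~ U[-0.1,0.1] mirrored."""
    rng = _rng_for(spec, rng)
    n = spec.n_nodes
    W = rng.uniform(-0.1, 0.1, size=(n, n))
    iu = np.triu_indices(n, k=1)
    W[(iu[1], iu[0])] = W[iu]  # mirror upper triangle into lower
    W[np.diag_indices(n)] = rng.uniform(-1.0, 1.0, size=n)
    return WeightMatrix(W, role="original_alpha", seed=spec.seed)


def generate_ar(spec: ConditionSpec, rng: np.random.Generator | None = None) -> WeightMatrix:
    """Asymmetric random: diag as SR; ordered off-diag = ±q + U[-0.1,0.1]."""
    rng = _rng_for(spec, rng)
    n = spec.n_nodes
    q = spec.q_magnitude * np.where(rng.random(size=(n, n)) < 0.5, 1.0, -1.0)
    W = q + rng.uniform(-0.1, 0.1, size=(n, n))
    W[np.diag_indices(n)] = rng.uniform(-1.0, 1.0, size=n)
    return WeightMatrix(W, role="original_alpha", seed=spec.seed)


def _module_mask(n: int, module_size: int) -> np.ndarray:
    mod = np.arange(n) // module_size
    return mod[:, None] == mod[None, :]


def generate_sm(spec: ConditionSpec, rng: np.random.Generator | None = None) -> WeightMatrix:
    """Symmetric modular: |alpha|=1 within modules, 0.01 between; signs
    positive with probability ``p_positive``, mirrored across the diagonal."""
    rng = _rng_for(spec, rng)
    n = spec.n_nodes
    assert spec.module_size is not None
    mag = np.where(_module_mask(n, spec.module_size), 1.0, 0.01)
    sign = np.where(rng.random(size=(n, n)) < spec.p_positive, 1.0, -1.0)
    iu = np.triu_indices(n, k=1)
    sign[(iu[1], iu[0])] = sign[iu]
    return WeightMatrix(mag * sign, role="original_alpha", seed=spec.seed)


def generate_am(spec: ConditionSpec, rng: np.random.Generator | None = None) -> WeightMatrix:
    """Asymmetric modular: SM draw plus independent U[-0.01,0.01] on each
    ordered off-diagonal entry; diagonal kept equal to the SM diagonal."""
    rng = _rng_for(spec, rng)
    sm = generate_sm(spec, rng)
    n = spec.n_nodes
    pert = rng.uniform(-0.01, 0.01, size=(n, n))
    pert[np.diag_indices(n)] = 0.0
    return WeightMatrix(sm.values + pert, role="original_alpha", seed=spec.seed)


_GENERATORS = {
    "SR": generate_sr,
    "AR": generate_ar,
    "SM": generate_sm,
    "AM": generate_am,
}


def generate(spec: ConditionSpec, rng: np.random.Generator | None = None) -> WeightMatrix:
    """Dispatch to the generator for ``spec.family``."""
    return _GENERATORS[spec.family](spec, rng)


def is_symmetric(W: WeightMatrix | np.ndarray, tol: float = 0.0) -> bool:
    """True when ``max |w_ij - w_ji| <= tol``."""
    values = W.values if isinstance(W, WeightMatrix) else np.asarray(W)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("matrix must be square")
    return bool(np.max(np.abs(values - values.T)) <= tol)
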