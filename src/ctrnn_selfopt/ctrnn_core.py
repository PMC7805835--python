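"""Continuous-time recurrent neural network (CTRNN) state and dynamics.

The network is a fully connected set of ``N`` leaky-integrator nodes

    tau_i * ds_i/dt = -s_i + sum_j w[j, i] * V_j,
    V_j = sigmoid(g_j * (s_j + theta_j)),

where ``w[i, j]`` is the connection strength *from* node ``i`` *to* node
``j`` (row = source, column = target; the input to node ``i`` is therefore
the ``i``-th column sum), ``tau_i`` is the activity decay constant, ``g_i``
the sigmoid gain and ``theta_i`` a fixed bias.  The sigmoid maps onto
``(-1, 1)`` so that with large gains the node outputs saturate near the
corners of the output hypercube, mimicking a discrete-state network.

Trajectories are integrated with the forward Euler method, either
synchronously (all nodes advanced from the old state) or asynchronously
(nodes advanced one at a time in a fresh random order, each seeing the
freshest activations).  Forward Euler is stable here when the step size is
smaller than twice the smallest time constant, which is enforced at
construction time.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import _kernels

__all__ = [
    "WeightMatrix",
    "NodeParams",
    "NetworkState",
    "RelaxationRecord",
    "sigmoid",
    "compute_bias",
    "node_outputs",
    "derivative",
    "euler_step",
    "relax",
    "relax_batch",
]

#: Residual threshold below which an endpoint counts as a fixed point,
#: in activation units per time unit (max-norm of ds/dt).
FIXED_POINT_TOL = 1e-6

Role = Literal["original_alpha", "current_omega"]
Mode = Literal["synchronous", "asynchronous"]


@dataclass
class WeightMatrix:
    """Square matrix of connection strengths with a bookkeeping role.

    ``role="original_alpha"`` marks the frozen matrix that defines the
    constraint problem; ``role="current_omega"`` marks the working copy
    modified by learning, whose entries stay within ``[-1, 1]``.
    """

    values: np.ndarray
    role: Role = "current_omega"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("weight matrix contains non-finite entries")
        if self.role not in ("original_alpha", "current_omega"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def as_omega(self) -> "WeightMatrix":
        """Deep-copied working matrix; the original stays untouched."""
        return WeightMatrix(self.values.copy(), role="current_omega", seed=self.seed)

    # -- serialization -------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write as delimited text with a commented header carrying metadata."""
        path = Path(path)
        with path.open("w", newline="") as fh:
            fh.write(f"# n_nodes={self.n_nodes}\n")
            fh.write(f"# role={self.role}\n")
            if self.seed is not None:
                fh.write(f"# seed={self.seed}\n")
            writer = csv.writer(fh)
            for row in self.values:
                writer.writerow([repr(float(x)) for x in row])

    @classmethod
    def from_csv(cls, path: str | Path) -> "WeightMatrix":
        path = Path(path)
        meta: dict[str, str] = {}
        rows: list[list[float]] = []
        with path.open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition("=")
                    meta[key.strip()] = val.strip()
                else:
                    rows.append([float(x) for x in line.split(",")])
        values = np.array(rows, dtype=np.float64)
        role = meta.get("role", "current_omega")
        seed = int(meta["seed"]) if "seed" in meta else None
        wm = cls(values, role=role, seed=seed)  # type: ignore[arg-type]
        if "n_nodes" in meta and int(meta["n_nodes"]) != wm.n_nodes:
            raise ValueError(
                f"header says n_nodes={meta['n_nodes']} but file has {wm.n_nodes} rows"
            )
        return wm

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_nodes": self.n_nodes,
            "role": self.role,
            "seed": self.seed,
            "values": self.values.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "WeightMatrix":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.array(payload["values"], dtype=np.float64),
            role=payload.get("role", "current_omega"),
            seed=payload.get("seed"),
        )


@dataclass
class NodeParams:
    """Per-node time constants, gains and biases, plus integration settings.

    Parameters
    ----------
    tau
        Activity decay constants, one per node, in time units; all > 0.
    gain
        Sigmoid gains, one per node, dimensionless; all > 0.
    bias
        Bias terms ``theta``, one per node.  Normally computed once from
        the original weights via :func:`compute_bias` and held fixed.
    dt
        Forward Euler step, in time units.  Must satisfy
        ``dt < 2 * min(tau)``.
    duration
        Length of one relaxation, in time units.
    """

    tau: np.ndarray
    gain: np.ndarray
    bias: np.ndarray
    dt: float = 0.1
    duration: float = 500.0

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=np.float64)
        self.gain = np.asarray(self.gain, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if not (self.tau.shape == self.gain.shape == self.bias.shape):
            raise ValueError("tau, gain and bias must have identical shapes")
        if np.any(self.tau <= 0):
            raise ValueError("all time constants must be positive")
        if np.any(self.gain <= 0):
            raise ValueError("all gains must be positive")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.dt >= 2.0 * float(self.tau.min()):
            raise ValueError(
                f"Euler step dt={self.dt} is unstable: must be < 2*min(tau)="
                f"{2.0 * float(self.tau.min())}"
            )

    @property
    def n_nodes(self) -> int:
        return self.tau.shape[0]

    @property
    def n_steps(self) -> int:
        """Number of Euler steps per relaxation (floor of duration/dt)."""
        return int(self.duration / self.dt + 1e-9)

    @classmethod
    def random(
        cls,
        n_nodes: int,
        rng: np.random.Generator,
        *,
        tau_range: tuple[float, float] = (1.0, 10.0),
        gain_range: tuple[float, float] = (10.0, 20.0),
        weights: "WeightMatrix | None" = None,
        dt: float = 0.1,
        duration: float = 500.0,
    ) -> "NodeParams":
        """Draw tau ~ U[1, 10] and gain ~ U[10, 20] per node; bias from
        the supplied weight matrix (zero if none given)."""
        tau = rng.uniform(*tau_range, size=n_nodes)
        gain = rng.uniform(*gain_range, size=n_nodes)
        bias = compute_bias(weights) if weights is not None else np.zeros(n_nodes)
        return cls(tau=tau, gain=gain, bias=bias, dt=dt, duration=duration)

    def with_bias_from(self, W: "WeightMatrix") -> "NodeParams":
        return replace(self, bias=compute_bias(W))


@dataclass
class NetworkState:
    """Activation vector ``s`` and the derived output vector ``V``.

    ``V`` is kept consistent with ``s`` at all times:
    ``V_j = sigmoid(g_j * (s_j + theta_j))``.
    """

    s: np.ndarray
    V: np.ndarray

    @classmethod
    def from_activations(cls, s: Sequence[float] | np.ndarray, params: NodeParams) -> "NetworkState":
        s = np.asarray(s, dtype=np.float64)
        return cls(s=s, V=node_outputs(s, params))


@dataclass
class RelaxationRecord:
    """Outcome of one relaxation: endpoint, convergence flag, score."""

    final_V: np.ndarray
    final_s: np.ndarray
    converged: bool
    satisfied_constraints: int = -1
    stage: str = ""


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite state encountered at Euler step {step}")


# ---------------------------------------------------------------------------
# elementary operations


def sigmoid(x):
    """Logistic sigmoid rescaled onto ``(-1, 1)``: ``2/(1+exp(-x)) - 1``.

    Odd and strictly increasing; equals ``tanh(x/2)``.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("sigmoid input must be finite")
    out = np.tanh(x / 2.0)  # identical to 2/(1+e^-x) - 1, numerically stable
    return out if out.ndim else float(out)


def compute_bias(W: WeightMatrix) -> np.ndarray:
    """Bias vector ``theta_i = -(1/2) * sum_j w[i, j]`` (half the row sum).

    Computed once from the original weights at construction and then held
    fixed, so the constraint problem stays stationary while learning
    modifies the working copy of the weights.
    """
    return -0.5 * W.values.sum(axis=1)


def node_outputs(s: np.ndarray, params: NodeParams) -> np.ndarray:
    """Componentwise output ``V_j = sigmoid(g_j * (s_j + theta_j))``."""
    return sigmoid(params.gain * (np.asarray(s, dtype=np.float64) + params.bias))


def derivative(state: NetworkState, W: WeightMatrix, params: NodeParams) -> np.ndarray:
    """Right-hand side ``ds_i/dt = (-s_i + sum_j w[j,i] V_j) / tau_i``."""
    if W.n_nodes != state.s.shape[0]:
        raise ValueError("weight matrix and state have mismatched sizes")
    return (-state.s + state.V @ W.values) / params.tau


def euler_step(
    state: NetworkState,
    W: WeightMatrix,
    params: NodeParams,
    mode: Mode = "asynchronous",
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """Advance the network by one Euler step of size ``params.dt``.

    In synchronous mode every node is advanced from the pre-step state.
    In asynchronous mode nodes are advanced one at a time in a fresh
    random permutation (Gauss-Seidel style), each update seeing the
    freshest activations and outputs.
    """
    dt = params.dt
    if mode == "synchronous":
        s_new = state.s + dt * derivative(state, W, params)
        return NetworkState.from_activations(s_new, params)
    if mode != "asynchronous":
        raise ValueError(f"unknown update mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng()
    s = state.s.copy()
    V = state.V.copy()
    Wv = W.values
    for i in rng.permutation(s.shape[0]):
        ds = (-s[i] + float(V @ Wv[:, i])) / params.tau[i]
        s[i] = s[i] + dt * ds
        V[i] = sigmoid(params.gain[i] * (s[i] + params.bias[i]))
    return NetworkState(s=s, V=V)


def _check_finite(s: np.ndarray, step: int) -> None:
    if not np.all(np.isfinite(s)):
        raise IntegrationError(step)


def relax(
    initial: NetworkState,
    W: WeightMatrix,
    params: NodeParams,
    mode: Mode = "asynchronous",
    rng: np.random.Generator | None = None,
) -> RelaxationRecord:
    """Integrate for ``floor(duration/dt)`` steps and report the endpoint.

    ``converged`` is true when the max-norm of the derivative at the final
    state is below the fixed-point tolerance; a false flag marks endpoints
    still in transit or on a non-fixed-point limit set.
    """
    n_steps = params.n_steps
    if rng is None:
        rng = np.random.default_rng()
    if mode == "synchronous":
        s = _kernels.relax_sync(
            initial.s.copy(), W.values, params.tau, params.gain, params.bias,
            params.dt, n_steps,
        )
    elif mode == "asynchronous":
        kernel_seed = int(rng.integers(0, 2**31 - 1))
        s = _kernels.relax_async(
            initial.s.copy(), W.values, params.tau, params.gain, params.bias,
            params.dt, n_steps, kernel_seed,
        )
    else:
        raise ValueError(f"unknown update mode {mode!r}")
    _check_finite(s, n_steps)
    state = NetworkState.from_activations(s, params)
    resid = np.max(np.abs(derivative(state, W, params)))
    return RelaxationRecord(
        final_V=state.V, final_s=state.s, converged=bool(resid < FIXED_POINT_TOL)
    )


def relax_batch(
    initial_s: np.ndarray,
    W: WeightMatrix,
    params: NodeParams,
    mode: Mode = "asynchronous",
    rng: np.random.Generator | None = None,
) -> list[RelaxationRecord]:
    """Relax a batch of initial activation row-vectors independently.

    Equivalent to calling :func:`relax` on each row; the batched kernel
    avoids per-trajectory Python overhead.
    """
    initial_s = np.atleast_2d(np.asarray(initial_s, dtype=np.float64))
    if rng is None:
        rng = np.random.default_rng()
    if mode == "synchronous":
        S = _kernels.relax_sync_batch(
            initial_s.copy(), W.values, params.tau, params.gain, params.bias,
            params.dt, params.n_steps,
        )
    elif mode == "asynchronous":
        seeds = rng.integers(0, 2**31 - 1, size=initial_s.shape[0])
        S = _kernels.relax_async_batch(
            initial_s.copy(), W.values, params.tau, params.gain, params.bias,
            params.dt, params.n_steps, seeds,
        )
    else:
        raise ValueError(f"unknown update mode {mode!r}")
    _check_finite(S, params.n_steps)
    records = []
    for s in S:
        state = NetworkState.from_activations(s, params)
        resid = np.max(np.abs(derivative(state, W, params)))
        records.append(
            RelaxationRecord(
                final_V=state.V, final_s=state.s,
                converged=bool(resid < FIXED_POINT_TOL),
            )
        )
    return records
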