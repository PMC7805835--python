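"""Numba-compiled inner loops for Euler relaxation.

A single relaxation is 5,000 small steps at the default settings and the
learning experiments run hundreds of thousands of them, so the stepping
loops are compiled.  Semantics are identical to the pure-Python
``euler_step`` path, which the tests cross-check step by step.

The asynchronous kernels draw their node-update permutations from numba's
internal legacy RNG, seeded per trajectory from the caller's generator, so
results are reproducible given the caller's seed.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def _sigmoid(x):
    return np.tanh(0.5 * x)


@njit(cache=False)
def relax_sync(s, W, tau, gain, bias, dt, n_steps):
    """All nodes advanced from the pre-step state, n_steps times."""
    n = s.shape[0]
    V = np.empty(n)
    for step in range(n_steps):
        for j in range(n):
            V[j] = _sigmoid(gain[j] * (s[j] + bias[j]))
        for i in range(n):
            total = 0.0
            for j in range(n):
                total += W[j, i] * V[j]
            s[i] = s[i] + dt * (-s[i] + total) / tau[i]
    return s


@njit(cache=False)
def relax_async(s, W, tau, gain, bias, dt, n_steps, seed):
    """Gauss-Seidel sweep: fresh random node order each step, freshest values."""
    np.random.seed(seed)
    n = s.shape[0]
    V = np.empty(n)
    for j in range(n):
        V[j] = _sigmoid(gain[j] * (s[j] + bias[j]))
    for step in range(n_steps):
        order = np.random.permutation(n)
        for k in range(n):
            i = order[k]
            total = 0.0
            for j in range(n):
                total += W[j, i] * V[j]
            s[i] = s[i] + dt * (-s[i] + total) / tau[i]
            V[i] = _sigmoid(gain[i] * (s[i] + bias[i]))
    return s


@njit(cache=False)
def relax_sync_batch(S, W, tau, gain, bias, dt, n_steps):
    for r in range(S.shape[0]):
        relax_sync(S[r], W, tau, gain, bias, dt, n_steps)
    return S


@njit(cache=False)
def relax_async_batch(S, W, tau, gain, bias, dt, n_steps, seeds):
    for r in range(S.shape[0]):
        relax_async(S[r], W, tau, gain, bias, dt, n_steps, seeds[r])
    return S
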