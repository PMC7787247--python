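"""Numba kernels for Glauber (heat-bath) single-spin-flip dynamics.

Each attempt picks a uniformly random site i and sets S_i = +1 with the
heat-bath probability

    p_open = 1 / (1 + exp(-2*beta*h_i)),   h_i = J*(S_{i-1}+S_{i+1}) + phi,

which satisfies detailed balance with respect to the ring Hamiltonian's
Boltzmann distribution.  Kernels use numba's internal np.random state,
seeded explicitly per call, so traces are bit-reproducible given a seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _attempts(spins, beta, coupling, phi, n_attempts):
    """Run n_attempts heat-bath updates in place."""
    n = spins.size
    for _ in range(n_attempts):
        i = np.random.randint(0, n)
        left = spins[i - 1] if i > 0 else spins[n - 1]
        right = spins[i + 1] if i < n - 1 else spins[0]
        h = coupling * (left + right) + phi
        p_open = 1.0 / (1.0 + np.exp(-2.0 * beta * h))
        spins[i] = 1 if np.random.random() < p_open else -1


@njit(cache=True)
def gating_trace_kernel(spins, beta, coupling, phi,
                        attempts_per_sample, n_samples, seed):
    """Sampled open-count trace: n_samples blocks of heat-bath attempts."""
    np.random.seed(seed)
    open_counts = np.empty(n_samples, dtype=np.int64)
    for k in range(n_samples):
        _attempts(spins, beta, coupling, phi, attempts_per_sample)
        c = 0
        for s in spins:
            if s == 1:
                c += 1
        open_counts[k] = c
    return open_counts


@njit(cache=True)
def circuit_kernel(spins_na, spins_k,
                   beta_na, j_na, e_na, g_max_na, attempts_na,
                   beta_k, j_k, e_k, g_max_k, attempts_k,  # per-step int64 arrays
                   c_m, g_leak, e_leak, v0, dt, stimulus, seed):
    """Exponential-Euler membrane integration interleaved with Glauber updates.

    At each step the two machines make their flip attempts at the current
    driving forces phi_gamma = V - E_gamma; their instantaneous open
    fractions set the conductances, then V is advanced by the exact
    constant-coefficient exponential update over dt.

    Returns (voltage, g_na, g_k) sampled at step starts; voltage has one
    extra trailing entry (the final state).  Aborts (flag -1 in the first
    return slot of g_na) if |V| exceeds 500 mV.
    """
    np.random.seed(seed)
    n_steps = stimulus.size
    n_na = spins_na.size
    n_k = spins_k.size
    voltage = np.empty(n_steps + 1)
    g_na_tr = np.empty(n_steps)
    g_k_tr = np.empty(n_steps)
    v = v0
    fail_step = -1
    for t in range(n_steps):
        voltage[t] = v
        _attempts(spins_na, beta_na, j_na, v - e_na, attempts_na[t])
        _attempts(spins_k, beta_k, j_k, v - e_k, attempts_k[t])
        open_na = 0
        for s in spins_na:
            if s == 1:
                open_na += 1
        open_k = 0
        for s in spins_k:
            if s == 1:
                open_k += 1
        g_na = g_max_na * open_na / n_na
        g_k = g_max_k * open_k / n_k
        g_na_tr[t] = g_na
        g_k_tr[t] = g_k
        g_tot = g_na + g_k + g_leak
        v_inf = (g_na * e_na + g_k * e_k + g_leak * e_leak
                 + stimulus[t]) / g_tot
        v = v_inf + (v - v_inf) * np.exp(-dt * g_tot / c_m)
        if np.abs(v) > 500.0:
            fail_step = t
            break
    voltage[min(n_steps, fail_step + 1) if fail_step >= 0 else n_steps] = v
    return voltage, g_na_tr, g_k_tr, fail_step
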