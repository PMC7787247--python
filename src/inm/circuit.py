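"""Single-compartment membrane circuit driven by two Ising Neural Machines.

The compartment carries a Na+ machine, a K+ machine and an ohmic leak on a
specific capacitance c_m.  Current conservation gives

    c_m dV/dt = -g_Na(t)(V - E_Na) - g_K(t)(V - E_K) - g_L(V - E_L) + I_ext

where each machine's conductance is g_max times its instantaneous open
fraction, and the open fractions evolve by Glauber dynamics driven by the
machine's own field phi_gamma = V - E_gamma.  Integration is fixed-step
exponential Euler on V (exact for frozen conductances) interleaved with
the machines' flip attempts each dt.

Because the gating field is referenced to the equilibrium potential, the
K+ machine is at least half open for any V above E_K: the resting state
sits close to E_K and excitability comes from the fast, steep Na+ machine
racing the slow (delayed-rectifier-like) K+ machine, in the style of
two-variable relaxation models.  A suprathreshold pulse produces an
all-or-none spike whose repolarization overshoots toward E_K
(after-hyperpolarization) while the K machine is transiently more open
than at rest; the machines' relaxation back to rest sets an absolute
refractory period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .errors import IntegrationError, ValidationError
from .ising import IsingParameters, open_fraction

__all__ = [
    "MachineSpec",
    "CircuitParams",
    "CircuitTrace",
    "rectangles_to_stimulus",
    "simulate_compartment",
    "detect_spikes",
    "measure_refractory_interval",
]


@dataclass(frozen=True)
class MachineSpec:
    """One Ising Neural Machine: chain size, couplings and kinetics.

    beta (mV^-1) sets the steepness of the machine's activation sigmoid,
    coupling J (mV) its cooperativity, flip_rate (1/ms) how fast its open
    fraction tracks the voltage.
    """

    n_channels: int = 1000
    coupling: float = 0.25
    beta: float = 0.02
    flip_rate: float = 1.0

    def __post_init__(self):
        if self.n_channels < 2:
            raise ValidationError("n_channels must be >= 2")
        if not self.coupling > 0:
            raise ValidationError("coupling must be > 0 (ferromagnetic)")
        if not (self.beta > 0 and self.flip_rate > 0):
            raise ValidationError("beta and flip_rate must be > 0")

    def ising_parameters(self, phi: float = 0.0,
                         e_gamma: float = 0.0) -> IsingParameters:
        return IsingParameters(self.n_channels, self.coupling, self.beta,
                               phi, e_gamma)


# Defaults: canonical squid-axon passive constants; machine steepness and
# the Na:K flip-rate ratio chosen so the compartment rests near E_K and
# fires all-or-none spikes (see docs/methods.md).
@dataclass(frozen=True)
class CircuitParams:
    """Full parameter set of the single-compartment circuit."""

    c_m: float = 1.0            # uF/cm^2
    g_leak: float = 0.3         # mS/cm^2
    e_leak: float = -54.4       # mV
    e_na: float = 50.0          # mV
    e_k: float = -77.0          # mV
    g_max_na: float = 120.0     # mS/cm^2
    g_max_k: float = 9.0        # mS/cm^2
    inm_na: MachineSpec = field(default_factory=lambda: MachineSpec(
        n_channels=10000, coupling=0.25, beta=0.022, flip_rate=8.0))
    inm_k: MachineSpec = field(default_factory=lambda: MachineSpec(
        n_channels=10000, coupling=0.25, beta=0.03, flip_rate=0.25))
    dt: float = 0.01            # ms
    duration: float = 60.0      # ms
    seed: int = 0
    v_init: float = -70.0       # mV

    def __post_init__(self):
        if not self.c_m > 0:
            raise ValidationError("c_m must be > 0")
        for name in ("g_leak", "g_max_na", "g_max_k"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.e_na > self.e_k:
            raise ValidationError("physiological ordering requires E_Na > E_K")
        if not self.dt > 0:
            raise ValidationError("dt must be > 0")
        if not self.duration >= self.dt:
            raise ValidationError("duration must be >= dt")


@dataclass(frozen=True)
class CircuitTrace:
    """Time series produced by one compartment simulation."""

    times: np.ndarray       # ms
    voltage: np.ndarray     # mV
    g_na: np.ndarray        # mS/cm^2
    g_k: np.ndarray         # mS/cm^2
    i_na: np.ndarray        # uA/cm^2 (positive outward)
    i_k: np.ndarray         # uA/cm^2
    i_leak: np.ndarray      # uA/cm^2
    stimulus: np.ndarray    # uA/cm^2
    spike_times: np.ndarray  # ms

    def __post_init__(self):
        n = len(self.times)
        for name in ("voltage", "g_na", "g_k", "i_na", "i_k", "i_leak",
                     "stimulus"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length differs from times")
        if np.any(np.diff(self.spike_times) <= 0):
            raise ValidationError("spike_times must be strictly increasing")


def rectangles_to_stimulus(rectangles, dt: float, duration: float) -> np.ndarray:
    """Sum of rectangular current pulses (t_start, t_end, amplitude) on the
    simulation grid; amplitudes in uA/cm^2."""
    n_steps = int(round(duration / dt))
    t = dt * np.arange(n_steps)
    stim = np.zeros(n_steps)
    for t0, t1, amp in rectangles:
        if t1 <= t0:
            raise ValidationError(f"pulse has t_end <= t_start: ({t0}, {t1})")
        stim[(t >= t0) & (t < t1)] += amp
    return stim


def _attempt_schedule(spec: MachineSpec, dt: float, n_steps: int) -> np.ndarray:
    """Per-step flip-attempt counts; cumulative rounding keeps the mean
    attempt rate exact even when N*flip_rate*dt is fractional."""
    per_step = spec.n_channels * spec.flip_rate * dt
    cum = np.round(per_step * np.arange(n_steps + 1)).astype(np.int64)
    return np.diff(cum)


def simulate_compartment(params: CircuitParams,
                         stimulus=None) -> CircuitTrace:
    """Integrate the compartment and return the full trace.

    `stimulus` is either None (zero current), a list of rectangles
    (t_start, t_end, amplitude), or an array of per-step current densities
    of length duration/dt.  Raises :class:`IntegrationError` if the voltage
    leaves +-500 mV (dt too large for stability).
    """
    n_steps = int(round(params.duration / params.dt))
    if stimulus is None:
        stim = np.zeros(n_steps)
    elif isinstance(stimulus, np.ndarray):
        if stimulus.size != n_steps:
            raise ValidationError(
                f"stimulus array must have {n_steps} steps, got {stimulus.size}")
        stim = stimulus.astype(float)
    else:
        stim = rectangles_to_stimulus(stimulus, params.dt, params.duration)

    ss = np.random.SeedSequence(params.seed)
    s_init, s_kernel = ss.spawn(2)
    rng = np.random.default_rng(s_init)
    # machines start near their stationary law at v_init (independent spins
    # at the mean open probability; they relax fully within the first ms)
    p_na = open_fraction(params.v_init - params.e_na,
                         params.inm_na.beta, params.inm_na.coupling)
    p_k = open_fraction(params.v_init - params.e_k,
                        params.inm_k.beta, params.inm_k.coupling)
    spins_na = np.where(rng.random(params.inm_na.n_channels) < p_na, 1, -1
                        ).astype(np.int64)
    spins_k = np.where(rng.random(params.inm_k.n_channels) < p_k, 1, -1
                       ).astype(np.int64)

    voltage, g_na, g_k, fail_step = _kernels.circuit_kernel(
        spins_na, spins_k,
        params.inm_na.beta, params.inm_na.coupling, params.e_na,
        params.g_max_na, _attempt_schedule(params.inm_na, params.dt, n_steps),
        params.inm_k.beta, params.inm_k.coupling, params.e_k,
        params.g_max_k, _attempt_schedule(params.inm_k, params.dt, n_steps),
        params.c_m, params.g_leak, params.e_leak,
        params.v_init, params.dt, stim,
        int(s_kernel.generate_state(1)[0]))
    if fail_step >= 0:
        raise IntegrationError(
            f"voltage left +-500 mV at step {fail_step} "
            f"(t = {fail_step * params.dt:.3f} ms); reduce dt")
    times = params.dt * np.arange(n_steps)
    v = voltage[:n_steps]
    i_na = g_na * (v - params.e_na)
    i_k = g_k * (v - params.e_k)
    i_leak = params.g_leak * (v - params.e_leak)
    spikes = detect_spikes(v, times=times)
    return CircuitTrace(times=times, voltage=v, g_na=g_na, g_k=g_k,
                        i_na=i_na, i_k=i_k, i_leak=i_leak, stimulus=stim,
                        spike_times=spikes)


def detect_spikes(voltage, threshold: float = 0.0,
                  min_separation: float = 2.0,
                  times=None, dt: float | None = None) -> np.ndarray:
    """Spike times from upward threshold crossings, merged within
    min_separation ms.  Deterministic."""
    v = np.asarray(voltage, dtype=float)
    if times is None:
        if dt is None:
            raise ValidationError("provide either times or dt")
        times = dt * np.arange(v.size)
    else:
        times = np.asarray(times, dtype=float)
    if v.size >= 2:
        step = float(np.min(np.diff(times)))
        if min_separation < step:
            raise ValidationError("min_separation must be >= the sampling step")
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    out = []
    for idx in up:
        t = times[idx]
        if not out or t - out[-1] >= min_separation:
            out.append(t)
    return np.asarray(out)


def measure_refractory_interval(params: CircuitParams, amplitude: float,
                                pulse_width: float = 1.0,
                                lo: float = 1.0, hi: float = 30.0,
                                tol: float = 0.25,
                                first_pulse_at: float = 5.0) -> float:
    """Operational refractory period by twin-pulse bisection.

    Two identical suprathreshold rectangles are applied; the inter-pulse
    interval is bisected between `lo` (one spike) and `hi` (two spikes) on
    a fixed seed.  Returns the boundary interval to within `tol` ms.
    """

    def n_spikes(gap: float) -> int:
        rects = [(first_pulse_at, first_pulse_at + pulse_width, amplitude),
                 (first_pulse_at + gap, first_pulse_at + gap + pulse_width,
                  amplitude)]
        dur = first_pulse_at + gap + pulse_width + 25.0
        tr = simulate_compartment(replace(params, duration=dur), rects)
        return len(tr.spike_times)

    if n_spikes(lo) != 1 or n_spikes(hi) < 2:
        raise ValidationError(
            "bracketing failed: need 1 spike at lo and 2 spikes at hi")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if n_spikes(mid) >= 2:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
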