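"""Stochastic single-channel gating: Glauber dynamics on the Ising chain.

Generates synthetic patch-clamp-style traces.  The kinetic scheme is
single-spin-flip heat-bath (Glauber) dynamics, whose stationary law is
exactly the Boltzmann distribution of the ring Hamiltonian, so long runs
reproduce the transfer-matrix magnetization.  Physical time enters through
a per-channel flip-attempt rate: N * flip_rate attempts per ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import ValidationError
from .ising import IsingParameters

__all__ = [
    "ELEMENTARY_CHARGE",
    "DynamicsConfig",
    "GatingTrace",
    "glauber_flip_probability",
    "simulate_gating",
    "ions_per_second",
    "empirical_magnetization",
]

#: Elementary charge, coulomb.
ELEMENTARY_CHARGE = 1.602176634e-19


@dataclass(frozen=True)
class DynamicsConfig:
    """Kinetic and recording parameters for a gating simulation.

    flip_rate : per-channel attempt rate, 1/ms (sets the dwell-time scale)
    dt        : recording resolution, ms
    duration  : total simulated time, ms
    seed      : RNG seed (mandatory for reproducibility)
    unit_current : single-open-channel current, pA (pA-scale microcurrents)
    """

    flip_rate: float = 1.0
    dt: float = 0.1
    duration: float = 100.0
    seed: int = 0
    unit_current: float = 6.6

    def __post_init__(self):
        if not self.flip_rate > 0:
            raise ValidationError(f"flip_rate must be > 0, got {self.flip_rate}")
        if not self.dt > 0:
            raise ValidationError(f"dt must be > 0, got {self.dt}")
        if not self.duration >= self.dt:
            raise ValidationError("duration must be >= dt")
        if not self.unit_current > 0:
            raise ValidationError("unit_current must be > 0")
        if int(self.seed) != self.seed or self.seed < 0:
            raise ValidationError("seed must be a non-negative integer")


@dataclass(frozen=True)
class GatingTrace:
    """Synthetic patch-clamp recording of one channel population.

    current is open_counts * unit_current elementwise, so the trace shows
    the discrete staircase of single-channel current levels.
    """

    times: np.ndarray          # ms
    open_counts: np.ndarray    # integers in [0, N]
    current: np.ndarray        # pA
    n_channels: int

    def __post_init__(self):
        if not (len(self.times) == len(self.open_counts) == len(self.current)):
            raise ValidationError("trace vectors must have equal length")
        if np.any(self.open_counts < 0) or np.any(self.open_counts > self.n_channels):
            raise ValidationError("open_counts must lie in [0, N]")


def glauber_flip_probability(left: int, right: int, phi: float,
                             beta: float, coupling: float) -> float:
    """Heat-bath probability that a spin ends up open (+1).

    Given neighbours (left, right), the local field is
    h = J*(S_left + S_right) + phi and the update sets S_i = +1 with
    probability 1/(1 + exp(-2*beta*h)) regardless of the current state,
    which satisfies detailed balance for the ring Hamiltonian.
    """
    h = coupling * (left + right) + phi
    return 1.0 / (1.0 + np.exp(-2.0 * beta * h))


def _attempt_schedule(n_channels: int, config: DynamicsConfig) -> np.ndarray:
    """Integer attempts per recording interval, preserving the mean rate.

    The expected number of attempts in one dt is N*flip_rate*dt, which need
    not be an integer; cumulative rounding distributes the remainder evenly.
    """
    n_samples = int(round(config.duration / config.dt))
    per_sample = n_channels * config.flip_rate * config.dt
    cum = np.round(per_sample * np.arange(n_samples + 1)).astype(np.int64)
    return np.diff(cum)


def simulate_gating(params: IsingParameters,
                    config: DynamicsConfig) -> GatingTrace:
    """Simulate stochastic gating and return the sampled current trace.

    Spins start from an unbiased random configuration; the open-channel
    count is recorded every config.dt ms after the interval's flip
    attempts.  Bit-reproducible for a fixed seed.
    """
    schedule = _attempt_schedule(params.n_channels, config)
    if schedule.size == 0:
        raise ValidationError("duration too short: no samples to record")
    rng = np.random.default_rng(config.seed)
    spins = rng.choice(np.array([-1, 1], dtype=np.int64), size=params.n_channels)
    kernel_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0])
    # constant attempts per sample lets one kernel call do the whole trace
    if np.all(schedule == schedule[0]):
        open_counts = _kernels.gating_trace_kernel(
            spins, params.beta, params.coupling, params.driving_force,
            int(schedule[0]), schedule.size, kernel_seed)
    else:
        _kernels._seed_rng(kernel_seed)
        open_counts = np.empty(schedule.size, dtype=np.int64)
        for k, n_att in enumerate(schedule):
            _kernels._attempts(spins, params.beta, params.coupling,
                               params.driving_force, int(n_att))
            open_counts[k] = int(np.sum(spins == 1))
    times = config.dt * np.arange(1, schedule.size + 1)
    current = open_counts * config.unit_current
    return GatingTrace(times=times, open_counts=open_counts,
                       current=current, n_channels=params.n_channels)


def ions_per_second(current_pa: float, valence: int) -> float:
    """Ion flux through a pore carrying `current_pa` picoamperes.

    flux = I / (|z| e); 6.6 pA of a monovalent ion is ~4.1e7 ions/s.
    """
    if valence == 0:
        raise ValidationError("valence must be non-zero")
    return current_pa * 1e-12 / (abs(valence) * ELEMENTARY_CHARGE)


def empirical_magnetization(trace: GatingTrace, n_channels: int,
                            burn_in: float | None = None
                            ) -> tuple[float, float]:
    """Time-average magnetization of a trace with autocorrelation-aware SE.

    The observable is M(t) = 2*open_count(t) - N.  The standard error is
    corrected by the integrated autocorrelation time (Sokal windowing,
    window c = 5), since successive samples of a Glauber chain are
    strongly correlated.

    Returns (mean, standard_error).  burn_in defaults to 10% of the trace.
    """
    duration = float(trace.times[-1])
    if burn_in is None:
        burn_in = 0.1 * duration
    if burn_in >= duration:
        raise ValidationError("burn_in must be shorter than the trace")
    m = 2.0 * trace.open_counts[trace.times > burn_in] - n_channels
    if m.size == 0:
        raise ValidationError("no samples left after burn-in")
    mean = float(np.mean(m))
    if m.size == 1 or np.allclose(m, m[0]):
        return mean, 0.0
    var = float(np.var(m, ddof=1))
    # integrated autocorrelation time via FFT, Sokal automatic window
    x = m - mean
    n = x.size
    f = np.fft.rfft(x, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n].real
    acf /= acf[0]
    tau = 1.0
    for w in range(1, n):
        tau = 1.0 + 2.0 * np.sum(acf[1:w + 1])
        if w >= 5.0 * tau:
            break
    tau = max(tau, 1.0)
    se = float(np.sqrt(var * tau / n))
    return mean, se
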