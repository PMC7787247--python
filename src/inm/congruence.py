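"""Hodgkin-Huxley limit curves and the Ising "congruence" fit.

The HH steady-state activation n_inf(V) = alpha/(alpha+beta) is, under
general thermodynamic (Boltzmann) assumptions, a two-state logistic of the
membrane potential.  The Ising open fraction with J = 0 is exactly that
logistic — (1 + tanh(beta*phi))/2 = 1/(1 + exp(-2*beta*phi)) — so the
cooperative chain (J > 0) is a strict superset of the Boltzmann sigmoid
family.  `fit_ising_to_sigmoid` fits the open fraction

    f(phi) = (1 + m(phi - offset; beta, J)) / 2

to a target activation curve by multi-start least squares and reports the
fitted (beta, J, offset) with the residual sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .errors import FitError, ValidationError
from .ising import magnetization_fraction, open_fraction

__all__ = [
    "HHBoltzmannParams",
    "n_inf_from_rates",
    "n_inf_boltzmann",
    "SigmoidFitResult",
    "fit_ising_to_sigmoid",
]


@dataclass(frozen=True)
class HHBoltzmannParams:
    """Two-state Boltzmann parameters (A1, A2, B1, B2, phi_T) of the HH
    steady-state activation curve."""

    a1: float
    a2: float
    b1: float
    b2: float
    phi_t: float = 25.0

    def __post_init__(self):
        if not (self.a1 > 0 and self.a2 > 0):
            raise ValidationError("amplitudes A1, A2 must be > 0")
        if not self.phi_t > 0:
            raise ValidationError("thermal voltage phi_T must be > 0")


def n_inf_from_rates(alpha, beta_rate):
    """Steady-state open fraction alpha/(alpha + beta) from HH rate constants."""
    alpha = np.asarray(alpha, dtype=float)
    beta_rate = np.asarray(beta_rate, dtype=float)
    if np.any(alpha < 0) or np.any(beta_rate < 0):
        raise ValidationError("rate constants must be >= 0")
    total = alpha + beta_rate
    if np.any(total == 0):
        raise ValidationError("alpha and beta cannot both be zero")
    out = alpha / total
    return out if out.ndim else float(out)


def n_inf_boltzmann(phi, params: HHBoltzmannParams):
    """Boltzmann form 1 / (1 + (A2/A1) * exp((B1-B2)*phi/phi_T))."""
    phi = np.asarray(phi, dtype=float)
    z = np.log(params.a2 / params.a1) + (params.b1 - params.b2) * phi / params.phi_t
    out = expit(-z)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SigmoidFitResult:
    """Fitted Ising sigmoid: open fraction (1 + m(phi - offset))/2."""

    beta: float          # mV^-1
    coupling: float      # mV (J; 0 recovers the pure Boltzmann logistic)
    offset: float        # mV, half-activation voltage
    rss: float
    n_points: int

    def predict(self, phi):
        return open_fraction(np.asarray(phi) - self.offset,
                             self.beta, self.coupling)

    def summary(self) -> str:
        return (
            "Ising sigmoid fit\n"
            f"  beta (1/mV)   : {self.beta:.6g}\n"
            f"  coupling J(mV): {self.coupling:.6g}\n"
            f"  offset (mV)   : {self.offset:.6g}\n"
            f"  RSS           : {self.rss:.6g}  over {self.n_points} points"
        )


_BETA_STARTS = (0.01, 0.03, 0.1, 0.3, 1.0)
_J_STARTS = (0.0, 1.0, 5.0, 10.0)


def _residuals(theta, phi, target, fix_j):
    log_beta, j, offset = theta
    beta = np.exp(log_beta)
    jj = fix_j if fix_j is not None else j
    return open_fraction(phi - offset, beta, jj) - target


def fit_ising_to_sigmoid(phi_grid, target, n_channels: int = 1,
                         fix_coupling: float | None = None
                         ) -> SigmoidFitResult:
    """Least-squares fit of the Ising open fraction to a target sigmoid.

    Multi-start (deterministic grid over beta and J) trust-region least
    squares on (log beta, J, offset); J is bounded below by 0, so the
    Boltzmann logistic is nested inside the search space.  Pass
    fix_coupling=0.0 to fit the pure tanh/logistic reference model.

    Returns the best :class:`SigmoidFitResult`; raises :class:`FitError`
    (carrying the best residual) if no start converges.
    """
    phi = np.asarray(phi_grid, dtype=float)
    y = np.asarray(target, dtype=float)
    if phi.size < 5:
        raise ValidationError("need at least 5 grid points to fit")
    if phi.size != y.size:
        raise ValidationError("phi_grid and target must have equal length")
    if np.any((y < 0) | (y > 1)):
        raise ValidationError("target values must lie in [0, 1]")

    mid = float(phi[np.argmin(np.abs(y - 0.5))])
    offsets = (mid, float(np.median(phi)))
    j_starts = (fix_coupling,) if fix_coupling is not None else _J_STARTS
    best = None
    best_cost = np.inf
    for b0 in _BETA_STARTS:
        for j0 in j_starts:
            for off0 in offsets:
                try:
                    res = least_squares(
                        _residuals, x0=(np.log(b0), j0, off0),
                        args=(phi, y, fix_coupling),
                        bounds=((np.log(1e-6), 0.0, phi.min() - 200.0),
                                (np.log(1e3), 100.0, phi.max() + 200.0)),
                        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
                except Exception:
                    continue
                if res.cost < best_cost:
                    best_cost = res.cost
                    best = res
    if best is None:
        raise FitError("all fit starts failed", best_rss=None)
    rss = float(2.0 * best.cost)
    coupling = 0.0 if fix_coupling == 0.0 else float(best.x[1])
    return SigmoidFitResult(beta=float(np.exp(best.x[0])),
                            coupling=coupling,
                            offset=float(best.x[2]),
                            rss=rss, n_points=phi.size)
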