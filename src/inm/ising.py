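"""Exact thermodynamics of a 1D periodic Ising chain of ion channels.

A population of N voltage-gated channels of one superfamily is modelled as a
closed ring of Ising spins, S_i = +1 open / -1 closed, with ferromagnetic
nearest-neighbour coupling J > 0 (channel cooperativity) and external field
phi = V - E_gamma, the electrochemical driving force in mV.  The Hamiltonian
is

    H = -J * sum_i S_i S_{i+1} - phi * sum_i S_i,      S_{N+1} = S_1.

The chain is solved exactly by the transfer matrix: closed forms for the
Helmholtz free energy A and the magnetization M = <sum_i S_i> are evaluated
in a numerically stable way for |beta*phi| up to ~700.  The magnetization,
rescaled to the open-channel fraction (1 + M/N)/2, defines the "Ising
conductance" of the membrane patch, and Ohm's law gives the membrane current
density.

beta plays the role of an inverse thermal voltage scale (mV^-1), so that
beta*phi and beta*J are dimensionless; J is therefore expressed in mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, ValidationError

__all__ = [
    "IsingParameters",
    "SpinConfiguration",
    "SliceGeometry",
    "hamiltonian_energy",
    "free_energy",
    "magnetization",
    "magnetization_fraction",
    "open_fraction",
    "brute_force_thermo",
    "ising_conductance",
    "membrane_current",
]

_BRUTE_FORCE_MAX_N = 16


@dataclass(frozen=True)
class IsingParameters:
    """Parameters of one channel superfamily's Ising chain.

    Attributes
    ----------
    n_channels : int
        Number of channels N on the ring (>= 2).
    coupling : float
        Ferromagnetic channel-channel interaction J > 0, in mV-equivalents.
    beta : float
        Inverse thermal voltage scale 1/phi_T, in mV^-1 (> 0).
    driving_force : float
        Electrochemical driving force phi = V - E_gamma, in mV.
    equilibrium_potential : float
        Superfamily equilibrium (Nernst) potential E_gamma, in mV.  Carried
        for bookkeeping; all thermodynamics depend on phi only.
    """

    n_channels: int
    coupling: float
    beta: float
    driving_force: float = 0.0
    equilibrium_potential: float = 0.0

    def __post_init__(self):
        if int(self.n_channels) != self.n_channels or self.n_channels < 2:
            raise ValidationError(
                f"n_channels must be an integer >= 2, got {self.n_channels}"
            )
        if not self.coupling > 0:
            raise ValidationError(
                f"coupling must satisfy the ferromagnetic constraint J > 0, "
                f"got {self.coupling}"
            )
        if not self.beta > 0:
            raise ValidationError(f"beta must be > 0, got {self.beta}")
        for name in ("coupling", "beta", "driving_force"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if not (np.isfinite(self.beta * self.coupling)
                and np.isfinite(self.beta * self.driving_force)):
            raise ValidationError("beta*J and beta*phi must be finite")

    def with_driving_force(self, phi: float) -> "IsingParameters":
        """Copy of these parameters at a different driving force."""
        return IsingParameters(
            self.n_channels, self.coupling, self.beta, phi,
            self.equilibrium_potential,
        )

    @classmethod
    def from_potentials(cls, n_channels, coupling, beta,
                        membrane_potential, equilibrium_potential):
        """Build parameters from V and E_gamma (phi = V - E_gamma)."""
        return cls(n_channels, coupling, beta,
                   membrane_potential - equilibrium_potential,
                   equilibrium_potential)


@dataclass(frozen=True)
class SpinConfiguration:
    """A length-N vector of +-1 gating states on a closed ring."""

    spins: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.spins, dtype=np.int64)
        if arr.ndim != 1 or arr.size == 0:
            raise ValidationError("spins must be a non-empty 1D vector")
        if not np.all(np.abs(arr) == 1):
            raise ValidationError("every spin must be +1 or -1")
        object.__setattr__(self, "spins", arr)

    def __len__(self) -> int:
        return self.spins.size

    @property
    def open_count(self) -> int:
        return int(np.sum(self.spins == 1))


@dataclass(frozen=True)
class SliceGeometry:
    """Geometry of the annular membrane slice hosting the ring of channels.

    Metadata only (radius ~10 um, thickness ~1 nm): no thermodynamic formula
    consumes it, but it is carried in provenance output.
    """

    radius_um: float = 10.0
    thickness_nm: float = 1.0

    def __post_init__(self):
        if not self.radius_um > 0:
            raise ValidationError("slice radius must be > 0")
        if not self.thickness_nm > 0:
            raise ValidationError("slice thickness must be > 0")


def hamiltonian_energy(config: SpinConfiguration,
                       params: IsingParameters) -> float:
    """Energy of one spin configuration, in driving-force (mV) units.

    H = -J * sum S_i S_{i+1} - phi * sum S_i with periodic wrap.
    """
    s = config.spins
    if s.size != params.n_channels:
        raise DimensionError(
            f"configuration has {s.size} spins but parameters declare "
            f"N = {params.n_channels} channels"
        )
    bond = float(np.sum(s * np.roll(s, -1)))
    return -params.coupling * bond - params.driving_force * float(np.sum(s))


def _stable_log_lambda(x, k):
    """log[cosh(x) + sqrt(sinh(x)^2 + exp(-4k))], overflow-free.

    x = beta*phi, k = beta*J.  Factor exp(|x|) out of the bracket so the
    expression stays finite for |x| up to ~700.
    """
    x = np.asarray(x, dtype=float)
    a = np.abs(x)
    em2a = np.exp(-2.0 * a)
    cosh_sc = 0.5 * (1.0 + em2a)           # cosh(x) * exp(-a)
    sinh_sc = 0.5 * (1.0 - em2a)           # |sinh(x)| * exp(-a)
    inner = np.sqrt(sinh_sc ** 2 + np.exp(-4.0 * k - 2.0 * a))
    return a + np.log(cosh_sc + inner)


def _transfer_matrix_pieces(x: float, k: float):
    """Stable ingredients of the 2x2 transfer matrix at x=beta*phi, k=beta*J.

    Returns (log lambda_plus, log rho, t_plus, t_minus) where
    rho = lambda_minus/lambda_plus in (0, 1) and t_pm = (dlambda_pm/dx) /
    lambda_plus.  Everything is evaluated with exp(|x|) factored out so
    |x| up to ~700 neither overflows nor loses the small eigenvalue
    (lambda_plus * lambda_minus = 2 sinh 2k exactly).
    """
    a = abs(x)
    em2a = np.exp(-2.0 * a)
    c_sc = 0.5 * (1.0 + em2a)          # cosh(x) * exp(-|x|)
    s_sc = 0.5 * (1.0 - em2a)          # |sinh(x)| * exp(-|x|)
    ek = np.exp(k)
    r_sc = np.sqrt((ek * s_sc) ** 2 + np.exp(-2.0 * k - 2.0 * a))
    lam_p_sc = ek * c_sc + r_sc
    log_lam_p = a + np.log(lam_p_sc)
    if k > 0:
        # det T = 2 sinh(2k) = lambda_plus * lambda_minus
        log_rho = np.log(2.0 * np.sinh(2.0 * k)) - 2.0 * log_lam_p
    else:
        log_rho = -np.inf              # free spins: lambda_minus = 0
    sgn = np.sign(x)
    ratio = ek * c_sc / r_sc
    t_plus = sgn * s_sc * ek * (1.0 + ratio) / lam_p_sc
    t_minus = sgn * s_sc * ek * (1.0 - ratio) / lam_p_sc
    return log_lam_p, log_rho, t_plus, t_minus


def free_energy(params: IsingParameters, *,
                thermodynamic_limit: bool = False) -> float:
    """Helmholtz free energy of the periodic chain.

    By default the exact finite-N partition function of the ring is used,
    Z = lambda_+^N + lambda_-^N (both transfer-matrix eigenvalues), which
    matches brute-force enumeration to round-off at any N.  With
    ``thermodynamic_limit=True`` only the dominant eigenvalue is kept,
    giving the large-N closed form

    A = -N*J - (N/beta) * log[cosh(beta*phi)
                              + sqrt(sinh(beta*phi)^2 + exp(-4*beta*J))].
    """
    n, j, b = params.n_channels, params.coupling, params.beta
    if thermodynamic_limit:
        log_lam = _stable_log_lambda(b * params.driving_force, b * j)
        return float(-n * j - (n / b) * log_lam)
    log_lam_p, log_rho, _, _ = _transfer_matrix_pieces(
        b * params.driving_force, b * j)
    log_z = n * log_lam_p + np.log1p(np.exp(n * log_rho))
    return float(-log_z / b)


def magnetization_fraction(phi, beta: float, coupling: float):
    """Per-spin magnetization m = M/N of the infinite-N transfer matrix.

    m = sinh(beta*phi) / sqrt(sinh(beta*phi)^2 + exp(-4*beta*J)).

    Vectorized in phi; coupling >= 0 is accepted here (J = 0 reduces to
    tanh(beta*phi), the non-cooperative Boltzmann limit).
    """
    if coupling < 0:
        raise ValidationError("coupling must be >= 0")
    x = np.asarray(beta * np.asarray(phi, dtype=float))
    a = np.abs(x)
    sinh_sc = np.sign(x) * 0.5 * (1.0 - np.exp(-2.0 * a))  # sinh(x)*exp(-a)
    denom = np.sqrt(sinh_sc ** 2 + np.exp(-4.0 * beta * coupling - 2.0 * a))
    # denom can underflow to 0 only where sinh also vanishes (m -> 0 there)
    with np.errstate(invalid="ignore"):
        out = np.where(denom > 0.0, sinh_sc / np.where(denom > 0, denom, 1.0),
                       0.0)
    return out if out.ndim else float(out)


def magnetization(params: IsingParameters, *,
                  thermodynamic_limit: bool = False) -> float:
    """M = <sum_i S_i> = -dA/dphi of the periodic chain.

    Exact finite-N by default (analytic derivative of log Z through both
    eigenvalues); with ``thermodynamic_limit=True`` the large-N closed
    form N*sinh(beta*phi)/sqrt(sinh^2(beta*phi) + exp(-4*beta*J)).
    """
    n = params.n_channels
    if thermodynamic_limit:
        return n * magnetization_fraction(
            params.driving_force, params.beta, params.coupling)
    _, log_rho, t_plus, t_minus = _transfer_matrix_pieces(
        params.beta * params.driving_force, params.beta * params.coupling)
    rho_nm1 = np.exp((n - 1) * log_rho)
    rho_n = np.exp(n * log_rho)
    return float(n * (t_plus + rho_nm1 * t_minus) / (1.0 + rho_n))


def open_fraction(phi, beta: float, coupling: float):
    """Mean open-channel fraction (1 + M/N)/2, in [0, 1]."""
    return 0.5 * (1.0 + magnetization_fraction(phi, beta, coupling))


def brute_force_thermo(params: IsingParameters) -> tuple[float, float]:
    """Exact (free_energy, magnetization) by enumerating all 2^N states.

    Independent oracle for the transfer-matrix closed forms; guarded to
    N <= 16 (65536 configurations).
    """
    n = params.n_channels
    if n > _BRUTE_FORCE_MAX_N:
        raise ValidationError(
            f"brute-force enumeration guarded to N <= {_BRUTE_FORCE_MAX_N}, "
            f"got N = {n}"
        )
    codes = np.arange(2 ** n, dtype=np.uint32)
    spins = (((codes[:, None] >> np.arange(n)) & 1) * 2 - 1).astype(np.int64)
    bond = np.sum(spins * np.roll(spins, -1, axis=1), axis=1)
    mag = np.sum(spins, axis=1)
    energy = -params.coupling * bond - params.driving_force * mag
    log_w = -params.beta * energy
    shift = log_w.max()
    w = np.exp(log_w - shift)
    z = w.sum()
    a = -(shift + np.log(z)) / params.beta
    m = float(np.sum(mag * w) / z)
    return float(a), m


def ising_conductance(params: IsingParameters, g_max: float) -> float:
    """Specific membrane conductance of the channel population, mS/cm^2.

    The signed magnetization is mapped to the open-channel fraction
    (1 + M/N)/2 and scaled by the superfamily's maximum specific
    conductance, so the result always lies in [0, g_max].  The raw signed
    magnetization remains available via :func:`magnetization`.
    """
    if not g_max > 0:
        raise ValidationError(f"g_max must be > 0, got {g_max}")
    frac = open_fraction(params.driving_force, params.beta, params.coupling)
    return float(g_max * frac)


def membrane_current(g: float, v: float, e_gamma: float) -> float:
    """Ohm's law for the membrane current density, uA/cm^2 (positive = outward).

    i_m = g * (V - E_gamma) with g in mS/cm^2 and potentials in mV.
    """
    if g < 0:
        raise ValidationError(f"conductance must be >= 0, got {g}")
    return g * (v - e_gamma)
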