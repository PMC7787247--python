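"""Cable theory of the myelinated axon and nuon (quasi-particle) kinematics.

The myelin sheath over an internode of length L is a series stack of
concentric cylindrical capacitor shells from the axon-core radius a1 to the
outer radius a2, giving a total capacitance

    C_m = c_m * 2*pi * d_m * L / ln(a2/a1).

Linear cable theory on the insulated internode reduces to a diffusion
equation dv/dt = D d2v/dx2 with diffusion coefficient

    D = a1^2 * ln(a2/a1) / (2 * c_m * r_L * d_m),

maximized over the core radius at a1 = a2 * e^{-1/2} ~ 0.61 a2.  The
conduction-velocity scaling (v ~ a2 myelinated, v ~ sqrt(a2) unmyelinated)
is applied relative to a user-supplied calibration point.

The nuon — the depolarization carrier plus its induced membrane
deformation, a polaron-like quasi-particle — is propagated kinematically
through a micro linear accelerator (muLINAC) picture: myelinated internodes
act as field-free drift tubes, and at each node of Ranvier a longitudinal
field E over the nodal gap adds kinetic energy q*E*gap.  Demyelinated
sections dissipate a fraction of the nuon's kinetic energy.  Each section's
velocity follows from E_i = (1/2) m v_i^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, SolverError, ValidationError

__all__ = [
    "MyelinGeometry",
    "CableParams",
    "NuonSection",
    "NuonKinematics",
    "myelin_capacitance",
    "diffusion_coefficient",
    "optimal_core_radius",
    "solve_cable",
    "gaussian_kernel_solution",
    "conduction_velocity",
    "accelerate_nuon",
    "calibrate_nuon",
]

_UM_TO_CM = 1e-4
_NM_TO_CM = 1e-7


@dataclass(frozen=True)
class MyelinGeometry:
    """Internode geometry: radii in um, lamella thickness in nm,
    per-surface capacitance in uF/cm^2."""

    a1_um: float                # axon-core radius
    a2_um: float                # outer (axon) radius
    length_um: float = 100.0    # internode length L
    lamella_thickness_nm: float = 10.0  # d_m
    c_m_area: float = 1.0       # uF/cm^2

    def __post_init__(self):
        if not 0 < self.a1_um < self.a2_um:
            raise GeometryError(
                f"need 0 < a1 < a2, got a1={self.a1_um}, a2={self.a2_um}")
        if not self.length_um > 0:
            raise GeometryError("length must be > 0")
        if not self.lamella_thickness_nm > 0:
            raise GeometryError("lamella thickness must be > 0")
        if not self.c_m_area > 0:
            raise GeometryError("c_m must be > 0")


@dataclass(frozen=True)
class CableParams:
    """Intracellular resistivity r_L, ohm*cm."""

    r_l: float = 100.0

    def __post_init__(self):
        if not self.r_l > 0:
            raise ValidationError("r_L must be > 0")


def myelin_capacitance(geom: MyelinGeometry) -> float:
    """Total series capacitance of the myelin sheath over one internode, pF.

    1/C_m integrates the reciprocal capacitances of concentric lamellae
    (each of thickness d_m, area 2*pi*a*L) from a1 to a2:
    C_m = c_m * 2*pi*d_m*L / ln(a2/a1).
    """
    c_m_f_per_cm2 = geom.c_m_area * 1e-6
    d_m_cm = geom.lamella_thickness_nm * _NM_TO_CM
    l_cm = geom.length_um * _UM_TO_CM
    c_farad = (c_m_f_per_cm2 * 2.0 * np.pi * d_m_cm * l_cm
               / np.log(geom.a2_um / geom.a1_um))
    return float(c_farad * 1e12)


def diffusion_coefficient(geom: MyelinGeometry,
                          cable: CableParams) -> float:
    """Cable diffusion coefficient D = a1^2 ln(a2/a1)/(2 c_m r_L d_m), cm^2/ms.

    a1 in um and d_m in nm are converted to cm; c_m (uF/cm^2) and r_L
    (ohm*cm) combine to give seconds (F*ohm), hence the final /1000 to ms.
    """
    a1_cm = geom.a1_um * _UM_TO_CM
    d_cm2_per_s = (a1_cm ** 2 * np.log(geom.a2_um / geom.a1_um)
                   / (2.0 * geom.c_m_area * 1e-6 * cable.r_l
                      * geom.lamella_thickness_nm * _NM_TO_CM))
    return float(d_cm2_per_s / 1e3)


def optimal_core_radius(a2_um: float) -> float:
    """Core radius maximizing D at fixed outer radius: a1 = a2 * e^{-1/2}.

    d/da1 [a1^2 ln(a2/a1)] = a1 (2 ln(a2/a1) - 1) = 0  =>  ln(a2/a1) = 1/2.
    The optimal ratio ~0.607 is independent of c_m, r_L and d_m.
    """
    if not a2_um > 0:
        raise ValidationError("a2 must be > 0")
    return float(a2_um * np.exp(-0.5))


def solve_cable(initial_v, d_coeff: float, t: float,
                domain: tuple[float, float], n_grid: int = 256,
                return_grid: bool = False):
    """Integrate dv/dt = D d2v/dx2 on [x_min, x_max] to time t (ms).

    Explicit central finite differences with an internal sub-step chosen
    for stability (D dt/dx^2 <= 0.4); Dirichlet boundaries clamped at the
    initial edge values.  `initial_v` is a callable of x (cm) or an array
    on the uniform grid.  Returns v(x, t) (and the grid if requested).
    """
    if t < 0:
        raise ValidationError("t must be >= 0")
    if n_grid < 16:
        raise ValidationError("n_grid must be >= 16")
    if d_coeff < 0:
        raise ValidationError("D must be >= 0")
    x = np.linspace(domain[0], domain[1], n_grid)
    dx = x[1] - x[0]
    v = np.array([initial_v(xi) for xi in x], dtype=float) \
        if callable(initial_v) else np.asarray(initial_v, dtype=float).copy()
    if v.size != n_grid:
        raise ValidationError("initial array must match n_grid")
    if t == 0 or d_coeff == 0:
        return (v, x) if return_grid else v
    dt_stable = 0.4 * dx * dx / d_coeff
    n_sub = max(1, int(np.ceil(t / dt_stable)))
    dt = t / n_sub
    r = d_coeff * dt / (dx * dx)
    if r > 0.5 + 1e-12:
        raise SolverError(f"stability violated after sub-stepping: r = {r:.3g}")
    for _ in range(n_sub):
        v[1:-1] = v[1:-1] + r * (v[2:] - 2.0 * v[1:-1] + v[:-2])
    return (v, x) if return_grid else v


def gaussian_kernel_solution(x, t: float, d_coeff: float,
                             sigma0: float, amplitude: float = 1.0,
                             center: float = 0.0):
    """Closed-form heat-kernel evolution of a Gaussian initial profile.

    A Gaussian of width sigma0 spreads to sigma(t) = sqrt(sigma0^2 + 2Dt)
    on an unbounded domain, conserving area.
    """
    var = sigma0 ** 2 + 2.0 * d_coeff * t
    return (amplitude * sigma0 / np.sqrt(var)
            * np.exp(-((np.asarray(x) - center) ** 2) / (2.0 * var)))


def conduction_velocity(a2_um: float, myelinated: bool,
                        reference: tuple[float, float]) -> float:
    """Velocity scaling law relative to a calibration point (a2_ref, v_ref).

    Myelinated axons: v proportional to the outer radius a2.
    Unmyelinated axons: v proportional to sqrt(a2).
    """
    a2_ref, v_ref = reference
    if not (a2_um > 0 and a2_ref > 0):
        raise ValidationError("radii must be > 0")
    if not v_ref > 0:
        raise ValidationError("reference velocity must be > 0")
    ratio = a2_um / a2_ref
    return float(v_ref * (ratio if myelinated else np.sqrt(ratio)))


@dataclass(frozen=True)
class NuonSection:
    """One internode drift tube: length (um) and the fraction of the
    nuon's kinetic energy dissipated inside it (0 = intact myelin)."""

    length_um: float = 100.0
    loss_coefficient: float = 0.0

    def __post_init__(self):
        if not self.length_um > 0:
            raise ValidationError("section length must be > 0")
        if self.loss_coefficient < 0 or self.loss_coefficient > 1:
            raise ValidationError("loss_coefficient must lie in [0, 1]")


@dataclass(frozen=True)
class NuonKinematics:
    """Nuon state along a muLINAC axon.

    Before acceleration only the structural fields are set; `accelerate_nuon`
    fills velocities (m/s), energies (J-equivalents) and positions (um).
    """

    effective_mass: float               # kg-equivalent m_n
    effective_charge: float             # C-equivalent q_n
    node_field: float                   # V/m at the nodes of Ranvier
    node_gap_um: float = 1.0            # nodal gap the field acts over
    sections: tuple[NuonSection, ...] = ()
    initial_velocity: float = 0.0       # m/s entering the first node
    velocities: np.ndarray | None = None    # m/s, per section
    energies: np.ndarray | None = None      # J, per section (post-loss)
    positions_um: np.ndarray | None = None  # um, section exit positions
    energy_gained: float = 0.0          # J, sum of nodal kicks
    energy_lost: float = 0.0            # J, sum of dissipative losses
    stalled: bool = False

    def __post_init__(self):
        if not self.effective_mass > 0:
            raise ValidationError("effective mass must be > 0")
        if not self.node_gap_um > 0:
            raise ValidationError("node gap must be > 0")
        if self.initial_velocity < 0:
            raise ValidationError("initial velocity must be >= 0")

    @property
    def terminal_velocity(self) -> float:
        if self.velocities is None:
            raise ValidationError("run accelerate_nuon first")
        return float(self.velocities[-1])

    @property
    def nodal_energy_gain(self) -> float:
        """Kinetic energy gained at one node: q * E * gap (J)."""
        return (self.effective_charge * self.node_field
                * self.node_gap_um * 1e-6)


def accelerate_nuon(kin: NuonKinematics) -> NuonKinematics:
    """Propagate the nuon through all sections, filling the kinematics.

    Per section i: a nodal kick adds q*E*gap to the kinetic energy, then a
    fraction loss_i of the post-kick energy is dissipated; the drift-tube
    velocity is v_i = sqrt(2 E_i / m).  Energy bookkeeping is exact:
    E_final = E_initial + sum(gains) - sum(losses).  A nuon whose energy
    reaches zero stalls (velocity clamped at 0, stalled flag set).
    """
    if not kin.sections:
        raise ValidationError("sections must be non-empty")
    gain = kin.nodal_energy_gain
    if gain < 0:
        raise ValidationError("nodal energy gain must be >= 0 "
                              "(check charge and field signs)")
    e = 0.5 * kin.effective_mass * kin.initial_velocity ** 2
    energies = np.empty(len(kin.sections))
    velocities = np.empty(len(kin.sections))
    positions = np.cumsum([s.length_um for s in kin.sections])
    total_gain = 0.0
    total_loss = 0.0
    stalled = False
    for i, sec in enumerate(kin.sections):
        e += gain
        total_gain += gain
        loss = sec.loss_coefficient * e
        e -= loss
        total_loss += loss
        energies[i] = e
        velocities[i] = np.sqrt(max(2.0 * e / kin.effective_mass, 0.0))
        if e <= 0.0:
            stalled = True
    return replace(kin, velocities=velocities, energies=energies,
                   positions_um=positions.astype(float),
                   energy_gained=total_gain, energy_lost=total_loss,
                   stalled=stalled)


def calibrate_nuon(target_velocity: float, sections, node_gap_um: float = 1.0,
                   effective_mass: float = 1e-20,
                   effective_charge: float = 1.602176634e-19
                   ) -> tuple[NuonKinematics, str]:
    """Solve for nodal parameters reproducing a target terminal velocity.

    Only the combination  q * E * gap * k_nodes / m = v_target^2 / 2  is
    identifiable from the kinematics when all sections are intact; mass,
    charge and field cannot be separated.  A representative triple is
    returned (mass and charge fixed at documented defaults, the node field
    solved for) together with a statement of the degeneracy.
    """
    if not target_velocity > 0:
        raise ValidationError("target velocity must be > 0")
    sections = tuple(sections)
    if len(sections) == 0:
        raise ValidationError("cannot calibrate with zero nodes")
    if any(s.loss_coefficient != 0 for s in sections):
        raise ValidationError("calibration assumes intact (loss-free) sections")
    k = len(sections)
    node_field = (0.5 * effective_mass * target_velocity ** 2
                  / (k * effective_charge * node_gap_um * 1e-6))
    kin = NuonKinematics(effective_mass=effective_mass,
                         effective_charge=effective_charge,
                         node_field=node_field, node_gap_um=node_gap_um,
                         sections=sections)
    degeneracy = (
        "only q*E*gap*k/m = v^2/2 is identified; (m, q, E) returned is one "
        "representative of a two-parameter family")
    return kin, degeneracy
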