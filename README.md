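# inm — Ising Neural Machines

Statistical-mechanics simulation of nerve-impulse generation and
propagation, built for computational neurophysiologists who want a
channel-population model that is *exactly solvable* at equilibrium and
*stochastic* in time.

The core idea: the N voltage-gated ion channels of one superfamily (Na⁺,
K⁺, …) on a thin annular slice of axon membrane are a one-dimensional
periodic Ising chain.  Each channel is a spin, S_i = +1 (open) or −1
(closed), with ferromagnetic coupling J > 0 (gating cooperativity) and an
external field equal to the electrochemical driving force φ = V − E_γ:

    H = −J Σᵢ S_i S_{i+1} − φ Σᵢ S_i ,     S_{N+1} = S_1

The ring is solved exactly by the transfer matrix — Helmholtz free energy
A(φ, β), magnetization M = ⟨Σ S_i⟩ = −∂A/∂φ — and the open-channel
fraction (1 + M/N)/2 scaled by a maximal specific conductance defines the
**Ising conductance** of the membrane patch; Ohm's law i_m = g·(V − E_γ)
gives the current density.  With J = 0 the open fraction collapses to the
Boltzmann/logistic activation curve of the Hodgkin–Huxley steady state
(the "congruence"); J > 0 sharpens it, so the classical sigmoid is nested
inside the Ising family.

Around this exact core the package provides:

- **Glauber gating dynamics** — heat-bath single-spin-flip Monte Carlo
  whose stationary law is exactly the chain's Boltzmann distribution;
  generates synthetic patch-clamp traces (pA staircase, ion-flux
  conversion: 6.6 pA of a monovalent carrier ≈ 4.1×10⁷ ions/s).
- **A spiking compartment** — two stochastic "Ising Neural Machines"
  (Na⁺ fast, K⁺ slow/delayed) plus leak on a membrane capacitance;
  exponential-Euler integration interleaved with the machines' flip
  attempts produces all-or-none action potentials with
  after-hyperpolarization and a measurable refractory period.
- **Cable theory of myelinated axons** — series capacitance of the
  myelin sheath, the internode diffusion equation ∂v/∂t = D ∂²v/∂x² with
  D = a₁² ln(a₂/a₁)/(2 c_m r_L d_m), the optimal core radius
  a₁ = a₂ e^{−1/2} ≈ 0.6 a₂, and the velocity scaling v ∝ a₂
  (myelinated) vs v ∝ √a₂ (unmyelinated).
- **Nuon kinematics** — the depolarization carrier plus its induced
  membrane deformation treated as a polaron-like quasi-particle
  accelerated through a micro-LINAC: internodes are field-free drift
  tubes, nodes of Ranvier apply energy kicks q·E·gap, demyelinated
  sections dissipate kinetic energy (E_i = ½ m v_i²).

## Worked example

All subcommands share one YAML/JSON config (see `examples/config.yaml`)
and one global seed that spawns an independent substream per module.

```bash
inm magnetization-scan --config examples/config.yaml --out scan.csv
```

writes one row per (β, J, φ) grid point:

```
beta,J,phi,free_energy,magnetization,conductance
0.5,1,-2,-304.09526556761352,-95.433442930630591,0.82198027248649064
0.5,1,-1,-213.68610499197729,-81.693280701851805,3.2952094736666719
...
```

At β = 0.5 mV⁻¹, J = 1 mV and φ = −2 mV, 95.4 of the N = 100 channels'
net magnetization points closed, so the conductance is only 0.82 of the
g_max = 36 mS/cm² ceiling; the scan traces the full sigmoid as φ crosses 0.

```bash
inm simulate-compartment --config examples/config.yaml --out trace.csv
```

integrates the two-machine compartment for 50 ms with a 250 µA/cm² pulse
at t = 20–21 ms and reports `compartment trace with 1 spike(s)`.  The
trace rests at −62.0 mV, peaks at +33.6 mV (overshoot toward
E_Na = +50 mV) and undershoots to −67.4 mV (after-hyperpolarization
toward E_K = −77 mV) before recovering.

```bash
inm cable-analysis --config examples/config.yaml --out cable.json
```

reports, for an internode with a₁ = 0.6 µm, a₂ = 1 µm, L = 100 µm,
d_m = 10 nm, c_m = 1 µF/cm², r_L = 100 Ω·cm:

```
capacitance_pF                      0.123
diffusion_coefficient_cm2_per_ms    0.00919
optimal_core_radius_um              0.6065
```

```bash
inm nuon-accelerate --config examples/config.yaml --out nuon.csv
```

calibrates the nodal field so an intact 100-node axon reaches the target
150 m/s and writes the per-section velocity/energy profile (the final row
reads `velocity_m_s = 150.0`).  Only the combination q·E·gap·k/m is
identifiable; the output records one representative (m, q, E) triple and
says so.

`inm simulate-gating` and `inm fit-congruence` complete the set: the
former writes a pA staircase trace, the latter fits the Ising open
fraction to an HH Boltzmann activation curve and reports the fitted
(β, J, offset) with its residual next to the J = 0 logistic reference.

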