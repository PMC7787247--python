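# Methods

## The channel chain and its exact solution

A population of N voltage-gated channels of one superfamily on an annular
membrane slice is a periodic 1D Ising chain: spin +1 = open, −1 = closed,
ferromagnetic coupling J > 0 between neighbouring channels, external
field φ = V − E_γ (mV).  Because the model mixes an interaction energy
and a millivolt driving force in one Hamiltonian, we treat β as the
reciprocal of an effective thermal *voltage* scale φ_T (so β has units
mV⁻¹ and J is expressed in mV); βJ and βφ are the only dimensionless
combinations that enter any result.

`free_energy` and `magnetization` evaluate the **exact finite-N**
partition function of the ring, Z = λ₊^N + λ₋^N with both transfer-matrix
eigenvalues; the widely quoted closed forms that keep only λ₊ are the
N → ∞ limit and are available behind `thermodynamic_limit=True`.  The
distinction matters at the accuracy we test: at N = 8, βJ = 1 the
sub-dominant eigenvalue still contributes at the 10⁻⁵ level, while the
finite-N forms agree with exhaustive 2^N enumeration to round-off
(≲10⁻¹⁴ relative).  Numerically, e^{|βφ|} is factored out of every
eigenvalue expression and λ₋ is obtained from the determinant identity
λ₊λ₋ = 2 sinh 2βJ, so fields up to |βφ| ≈ 700 neither overflow nor lose
the small eigenvalue to cancellation.

The signed magnetization is mapped to a conductance through the open
fraction: g = g_max·(1 + M/N)/2 ∈ [0, g_max].  A literal identification
g := M would be negative for φ < 0 and dimensionless, hence unusable in
Ohm's law; the open-fraction rescaling preserves the sigmoid shape and
the saturation limits while giving g physical units.  The raw M remains
available.

## Glauber gating dynamics

No kinetic scheme is implied by the equilibrium model, so the dynamics is
a design choice: heat-bath (Glauber) single-spin-flip updates, in which a
uniformly chosen channel is re-sampled from its local conditional
equilibrium p(open) = 1/(1 + e^{−2β(J(S_left+S_right)+φ)}).  This is the
weakest-assumption Markov dynamics whose stationary law is exactly the
chain's Boltzmann distribution (detailed balance is checked analytically
over all neighbour configurations in the tests).  Physical time enters
through a per-channel attempt rate k_gate (default 1 ms⁻¹): N·k_gate
attempts per ms, so a channel's correlation time is ~1/k_gate ms and
dwell times are on the millisecond scale typical of single-channel
recordings.  Sampling every dt uses cumulative rounding of the attempt
count so fractional attempts-per-sample never bias the rate.  Traces are
bit-reproducible given a seed (the kernels seed numba's internal RNG
state explicitly).

The synthetic patch-clamp trace is open_count × unit current; the default
6.6 pA per open pore corresponds to ≈4.1×10⁷ monovalent ions/s
(i/(|z|e), e = 1.602176634×10⁻¹⁹ C).  Long-run means are compared to the
exact magnetization with an autocorrelation-corrected standard error
(integrated autocorrelation time by FFT with Sokal's window, c = 5),
since successive Glauber samples are strongly correlated.

What the generator does *not* emulate: sub-conductance levels, a separate
inactivated state, open-channel noise, or series-resistance filtering.
Passing tests therefore certify the Markov chain's consistency with the
equilibrium theory, not fidelity to any particular recording.

## The spiking compartment

Current conservation on a single patch:
c_m dV/dt = −g_Na(V−E_Na) − g_K(V−E_K) − g_L(V−E_L) + I_ext, with each
conductance equal to g_max times the *instantaneous* open fraction of its
machine, whose Glauber field is the machine's own driving force
φ_γ = V − E_γ.  Integration is fixed-step exponential Euler on V (exact
for frozen conductances; unconditionally stable) interleaved with each
machine's flip attempts every dt = 0.01 ms.

A structural consequence of gating on φ_γ = V − E_γ is that the K⁺
machine's half-activation sits at E_K, so K is at least half open
whenever V > E_K and the compartment rests near (but above) E_K — unlike
the HH fit, where the K activation midpoint is ~25 mV above rest and
n⁴ ≈ 0.01 at rest.  Excitability therefore has the structure of a
two-variable relaxation model: a fast, steep Na⁺ machine races a slow
("delayed") K⁺ machine.  The default machine parameters were chosen by a
nullcline analysis of the deterministic mean-field limit of *this exact
model* so that the resting state is stable, a strong pulse triggers a
regenerative upstroke, and the slow K recovery produces an
after-hyperpolarization and an absolute refractory period:

| parameter | Na⁺ machine | K⁺ machine | units |
|---|---|---|---|
| β (sigmoid steepness) | 0.022 | 0.03 | mV⁻¹ |
| J (cooperativity) | 0.25 | 0.25 | mV |
| flip rate | 8 | 0.25 | ms⁻¹ |
| g_max | 120 | 9 | mS/cm² |
| N (channels) | 10000 | 10000 | — |

Passive constants are the canonical squid values (c_m = 1 µF/cm²,
g_L = 0.3 mS/cm², E_L = −54.4, E_Na = +50, E_K = −77 mV) and
g_max_Na = 120 mS/cm² likewise.  g_max_K is smaller than the canonical
36 mS/cm² because here the *resting* K conductance is ≥ g_max_K/2 (see
above); at 36 the K branch overwhelms the maximal Na inward current at
every voltage and the compartment cannot fire at all.  With g_max_K = 9
the resting K conductance (~4.6 mS/cm²) is comparable to the total
resting conductance of the classical description, and the compartment
rests at ≈ −62 mV, fires all-or-none spikes peaking above +30 mV,
undershoots toward E_K, and shows a ~5 ms twin-pulse refractory interval.
For the same reason the Na:K flip-rate ratio is 32:1 rather than a small
ratio: the K machine doubles as the recovery variable, and its ~4 ms
relaxation sets the after-hyperpolarization depth and refractory period.
N = 10⁴ channels per machine keeps the open-fraction fluctuations
(σ ≈ √(f(1−f)/N)) small enough that noise does not trigger rebound
spikes during recovery; all of these are config knobs, not fitted
constants.

Spike detection is an upward threshold crossing (default 0 mV) with
crossings merged within a minimum separation; the refractory interval is
measured operationally by bisecting the twin-pulse spacing between
one-spike and two-spike outcomes on a fixed seed.  Slice-to-slice
coupling (propagation of the full stochastic circuit) is out of scope;
propagation is handled kinematically below.

## Cable theory and the myelin sheath

The sheath over an internode of length L is a series stack of concentric
lamellae (thickness d_m, per-area capacitance c_m) from the core radius
a₁ to the outer radius a₂: 1/C_m = ln(a₂/a₁)/(c_m 2π d_m L).  The
discrete 1000-shell series sum agrees with the closed form to <10⁻⁵
relative.  Linear cable theory then gives ∂v/∂t = D ∂²v/∂x² with
D = a₁² ln(a₂/a₁)/(2 c_m r_L d_m); all unit conversions (µm, nm → cm;
µF·Ω → ms) are centralized in two module constants, and D is reported in
cm²/ms.  D is maximized over the core radius at a₁/a₂ = e^{−1/2} ≈ 0.607
(from d/da₁[a₁² ln(a₂/a₁)] = 0), independent of every other parameter.

The solver is explicit central differences with an internal sub-step
keeping D·dt/dx² ≤ 0.4, plus the closed-form heat-kernel solution for
unbounded domains; the σ²(t) = σ²(0) + 2Dt variance law holds to <1%
before boundary influence.  Conduction velocity is exposed only as a
*scaling law* relative to a user-supplied calibration point — v ∝ a₂
myelinated, v ∝ √a₂ unmyelinated — because the theory fixes no
proportionality constant.

## Nuon kinematics (µLINAC)

The nuon — depolarization carrier plus induced membrane deformation,
treated as a classical quasi-particle of effective mass m and charge q —
traverses alternating nodes and internodes.  Each node applies a kinetic
energy kick ΔE = q·E·gap; each internode i (drift tube) is field-free
and, if demyelinated, dissipates a fraction `loss_coefficient` of the
nuon's current kinetic energy; the section velocity is
v_i = √(2E_i/m).  The fractional-loss form is our concretization of
dissipative damage — it guarantees E ≥ 0, makes total loss (coefficient
1) stall the nuon, and makes terminal velocity monotone non-increasing in
every section's loss.  Bookkeeping is exact by construction:
E_final = ΣΔE_gained − ΣΔE_lost.

Calibration to a target velocity is deliberately reported as a
one-parameter family: with k intact sections, the kinematics determine
only q·E·gap·k/m = v²/2, so mass, charge and field cannot be separated;
the returned triple fixes m and q at documented defaults (10⁻²⁰ kg,
one elementary charge) and solves for E, with the degeneracy stated in
the return value.  Node gap 1 µm and internode length 100 µm are
textbook-scale defaults.  The feedback of the deformation on the carrier
(a coupling Hamiltonian) has no concrete form in this framework and is
not modelled.

## Problem sizes and determinism

Enumeration oracles run to N = 12 (4096 states; N ≤ 16 guarded).
Stochastic consistency uses 10⁵ sweeps of N = 50–100 chains; compartment
runs are 30–60 ms at dt = 0.01 ms with 10⁴-channel machines.  One global
seed spawns per-module substreams via `SeedSequence` keyed on the module
name, so outputs are bit-reproducible and adding a module never perturbs
another's draws.

## Known limitations

- The equilibrium theory is one-dimensional with nearest-neighbour
  coupling only; no 2D membrane lattices, no antiferromagnetic regime.
- The compartment has no Na⁺ inactivation gate; repolarization relies
  entirely on the delayed K machine, so very long suprathreshold
  stimuli produce repetitive firing rather than block.
- Velocity calibration is relative; absolute nuon parameters are not
  identifiable and are never fabricated.
- The cable solver is linear (passive internode); active nodal channel
  clusters are not spatially modelled.
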