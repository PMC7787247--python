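# Shared configuration for the `inm` CLI.  Any block may be omitted;
# documented defaults are filled in.  JSON works too (it is valid YAML).
seed: 11

ising:
  n_channels: 100
  beta_grid: [0.5, 1.0, 2.0]     # 1/mV: three "temperatures"
  coupling_grid: [1.0]           # J, mV
  phi: [-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0]
  g_max: 36.0                    # mS/cm^2

gating:
  n_channels: 8
  coupling: 1.0
  beta: 1.0
  phi: 0.0                       # V at the equilibrium potential
  flip_rate: 1.0                 # per-channel attempts / ms
  dt: 0.5
  duration: 200.0
  unit_current: 6.6              # pA per open channel

congruence:
  phi_min: -100.0
  phi_max: 100.0
  n_points: 101
  a1: 1.0                        # HH Boltzmann amplitudes / exponents
  a2: 1.5
  b1: -2.0
  b2: 0.0
  phi_t: 25.0                    # thermal voltage, mV

circuit:
  duration: 50.0
  stimulus: [[20.0, 21.0, 250.0]]   # (t_start, t_end, uA/cm^2)

cable:
  a1_um: 0.6
  a2_um: 1.0
  r_l: 100.0                     # ohm*cm

nuon:
  n_sections: 100
  target_velocity_m_s: 150.0
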