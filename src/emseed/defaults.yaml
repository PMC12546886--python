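# Shipped defaults: physics constants, per-variety calibration,
# optimizer and network settings.  Any subset may be overridden by a
# user-supplied YAML file.

physics:
  coil:
    radius_m: 0.10
    separation_m: 0.10        # Helmholtz condition z = R
    coil_resistance_ohm: 3.0
    n_turns: 500
    wire_diameter_mm: 1.2
  seed_mechanics:
    V_seed: 2.5e-07           # m^3, single corn seed
    rho_seed: 1250.0          # kg/m^3
    f_n: 300.0                # Hz (fallback; varieties carry their own)
    zeta: 0.05
  impedance_ohm: 10.0         # voltage -> current map I = V/Z
  losses:
    switching_loss_W: 1.0
    control_power_W: 0.5

# Per-variety phenotype calibration.  Control means and maximal gains are
# the calibration targets; d_opt null means "compute the effective dose of
# the reference protocol at load time" so physics and calibration stay
# consistent.  dispersion is the replicate-mean SD in %-points, matched to
# the calibration 95% CI half-widths for n=3 replicates
# (hw * sqrt(3) / t_{0.975,2}).
varieties:
  - name: zhengdan958
    control_germination_pct: 82.4
    control_vigor_index: 76.2
    delta_g_max: 11.7
    delta_vi_max: 13.5
    gamma: 1.5
    f_n: 300.0
    zeta: 0.05
    dispersion: 1.05
    k: 0.9
    t50: 5.0
    d_opt: null
    reference_protocol:
      field_strength_mT: 3.5
      frequency_Hz: 300.0
      duration_s: 180.0
      voltage_amplitude_V: 27.5
      pulse_width_ms: 5.0
      duty_cycle_pct: 50.0
  - name: xianyu335
    control_germination_pct: 79.8
    control_vigor_index: 73.5
    delta_g_max: 11.5
    delta_vi_max: 13.3
    gamma: 1.5
    f_n: 280.0
    zeta: 0.05
    dispersion: 1.09
    k: 0.85
    t50: 5.4
    d_opt: null
    reference_protocol:
      field_strength_mT: 3.5
      frequency_Hz: 280.0
      duration_s: 180.0
      voltage_amplitude_V: 27.5
      pulse_width_ms: 5.0
      duty_cycle_pct: 50.0
  - name: jingke968
    control_germination_pct: 85.2
    control_vigor_index: 78.9
    delta_g_max: 11.5
    delta_vi_max: 13.5
    gamma: 1.5
    f_n: 320.0
    zeta: 0.05
    dispersion: 1.01
    k: 0.95
    t50: 4.7
    d_opt: null
    reference_protocol:
      field_strength_mT: 3.5
      frequency_Hz: 320.0
      duration_s: 180.0
      voltage_amplitude_V: 27.5
      pulse_width_ms: 5.0
      duty_cycle_pct: 50.0

optimizer:
  ga_pop_size: 50
  crossover_p: 0.8
  mutation_p: 0.02
  tournament_k: 3
  eta_c: 15.0
  eta_m: 20.0
  swarm_size: 30
  inertia_start: 0.9
  inertia_end: 0.4
  c1: 2.0
  c2: 2.0
  v_max_fraction: 0.2
  migration_interval: 10
  migration_count: 5
  archive_capacity: 200
  max_iters: 100
  adapt:
    alpha: 0.7
    beta: 0.3
    window: 10
    hv_stagnation_tol: 1.0e-09
    mutation_cap: 0.2
    crossover_floor: 0.6
    diversity_threshold: 0.05

network:
  image_shape: [64, 64, 3]
  sequence_shape: [50, 128]
  conv_channels: [32, 64]
  projection_channels: 8     # 1x1 conv before flatten -> 16*16*8 = 2048
  lstm_hidden: [256, 128]
  fc_hidden: 512
  n_targets: 8
  attention_dk: 128

training:
  lr_min: 1.0e-04
  lr_max: 8.0e-03
  cycle: 440        # one full decay over 10 epochs x 44 steps at batch 32
  max_epochs: 10
  clip_norm: 1.0
  batch_size: 32
  split_fractions: [0.70, 0.15, 0.15]
  lambda_reg: 1.0e-04
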