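# A complete synthetic "virtual material": every generator parameter the
# simulate subcommand uses, plus the analysis windows for each subcommand.
# Ground truth: Tg 400 K, bond breakage rate 1/ns, E 3 GPa, nu 0.3,
# D 0.1 nm^2/ns (= 1e-6 cm^2/s).

simulate:
  seed: 0
  tg_K: 400.0
  slope_low: 1.0e-4        # cm^3/(g K), glassy branch
  slope_high: 3.0e-4       # cm^3/(g K), rubbery branch
  v_at_tg: 0.54            # cm^3/g
  vt_noise_sd: 5.0e-4      # cm^3/g
  n_bonds: 500
  n_frames: 1001
  dt_ns: 0.01
  k_break: 1.0             # 1/ns
  k_reform: 0.0
  E_true_GPa: 3.0
  strain_yield: 0.05
  sigma_plateau_GPa: 0.15
  stress_noise_sd: 0.01    # GPa
  nu_true: 0.3
  L0_nm: 5.0
  n_strain_points: 400
  n_pack_atoms: 60
  pack_radius_nm: 0.15
  pack_box_nm: 2.5
  pack_strains: [0.0, 0.25, 0.5]
  D_true_nm2ns: 0.1
  n_chains: 50
  traj_frames: 501
  traj_dt_ns: 0.02

tg:
  low: "150:275"
  high: "475:600"

alpha:
  t1: 300.0
  t2: 325.0

mech:
  halfwidth: 0.025
  efit: "0.003:0.03"
  nufit: "0.01:0.02"
  maxs: "0.03:0.97"

freevol:
  probes: "0.1,0.05,0.01"
  spacing: 0.02

diffusion:
  window: "0.1:0.9"
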