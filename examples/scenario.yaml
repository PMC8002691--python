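# A single-station synthetic scenario for `tracern2o simulate --scenario`.
# Pathway rates decline with in-situ O2 as R_max * exp(-O2 / k_o2_uM);
# fungal denitrification is less O2-sensitive than bacterial.
noise:
  delta_sigma_permil: 2.0     # instrument delta-15N precision
  n2o_cv: 0.02                # multiplicative N2O quantity noise
  detection_limit_nmolN: 1.0
stations:
  - name: DemoStation
    depths_m: [60, 75, 85, 92, 98, 104, 112, 130]
    o2: {surface_uM: 200.0, center_m: 80.0, scale_m: 5.0}
    fungal: {r_max: 1.2, k_o2_uM: 2.0}
    bacterial: {r_max: 40.0, k_o2_uM: 0.5}
    nitrification: {r_max: 5.0, k_o2_uM: 30.0}
    z_top_m: 60.0
    no3_surface_umolL: 15.0
    no3_slope_umolL_per_m: 0.05
    background_n2o_nM: 50.0
    background_delta15n_permil: 0.0
    cap_leakage_fraction: 0.0
    timepoints_h: [0, 12, 24]
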