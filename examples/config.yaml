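# Run configuration: isotope constants, tracer additions, detection limits.
# Values shown are the package defaults (the cruise design).
r_ref: 0.0036765          # 15N/14N of the reference gas (AIR)
r_air: 0.0036765          # 15N/14N of atmospheric N2 (natural abundance)
liquid_volume_L: 0.118    # 120 mL bottle minus 2 mL helium headspace
tracer_no3:
  added_nmol: 500.0       # 0.1 mL of 5 mM 15N-potassium nitrate
  purity_fraction: 0.99
tracer_nh4:
  added_nmol: 80.0        # 0.1 mL of 0.8 mM 15N-ammonium chloride
  purity_fraction: 0.99
detection_limit_nmolN: 1.0   # N2O detection limit (nmol N)
no3_detection_umolL: 0.2     # ambient nitrate detection limit
nh4_detection_umolL: 0.015   # ambient ammonium detection limit (15 nM)
o2_threshold_uM: 1.0         # oxic-anoxic interface criterion
f15_includes_ambient: true   # dilute tracer f15 by the ambient pool
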