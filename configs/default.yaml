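# Default study conditions for the noctura simulator and pipeline.
# Values mirror the emulated selection design: 300 males phenotyped per
# cycle, the 25 most extreme selected and crossed to unselected females,
# 10 cycles; base population crepuscular (ND ratio ~ 1.0).
simulation:
  n_pop: 300
  n_selected: 25
  n_cycles: 10
  h2: 0.14            # base-population narrow-sense heritability of ND
  nd_mean: 1.0        # crepuscular baseline night/day ratio
  vp: 0.0225          # phenotypic variance of ND (sd 0.15)
  total_activity_per_day: 1500.0   # expected beam breaks per fly per day
  masking_m: 1.0      # light-masking strength (0 = none)
  tau_mean: 24.0      # free-running period, hours
  tau_sd: 0.2
  bump_phases: [0.0, 12.0]   # morning/evening activity bumps (ZT hours)
  bump_concentration: 2.0
  measurement_sd: 0.0 # extra assay noise on the fast phenotype path
  full_sib_mates: false
  nd_floor: 0.01
  seed: 0

thresholds:
  rhythm_alpha: 0.05       # Fisher g-test rhythmicity cut-off
  significance_alpha: 0.05
  period_search: {p_min: 18.0, p_max: 30.0, step: 0.1}
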