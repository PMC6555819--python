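# Small demonstration run: reduced library (6 seeds per spacer, DR0-DR2),
# full-site scenario, enrichment benchmark included.
seed: 7
design:
  seeds_per_spacer: 6
  spacer_range: [0, 2]
  n_background: 120
simulate:
  scenario: full
  sigma: 0.1
normalize:
  orientation: [o1]
  scale: log
motifs:
  beta_numerator: 15.0
  background: ht29
  pseudocount: 0.001
modes:
  z_threshold: 3.0
  engage_frac: 0.25
  engage_abs: 2.0
enrich:
  enabled: true
  n_pos: 150
  n_neg: 150
  region_len: 150
  planted_fraction: 0.9
  n_models: 1
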