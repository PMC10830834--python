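# Demo configuration: small synthetic breeding program + full analysis.
#   breedgain simulate --config demo.yaml --out demo_sim
#   breedgain run --config demo.yaml
seed: 7

sim:
  n_founders: 16
  crosses_per_year: 15
  n_years_crossing: 6
  n_trial_years: 6
  entries_per_trial: 50

paths:
  pheno: demo_sim/phenotypes.csv
  pedigree: demo_sim/pedigree.csv
  output: demo_out

qc:
  alpha: 0.05
  max_missing: 0.20

model:
  season_role: random
  use_dtf: true
  use_pedigree: true

trend:
  regressor: origin
  baseline_rule: mean_of_values

panel:
  rel_threshold: 0.4
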