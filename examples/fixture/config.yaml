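# Demo pipeline configuration for the shipped synthetic fixture.
inputs:
  abundance: asv_table.tsv
  taxonomy: taxonomy.tsv
  metadata: metadata.tsv
filter:
  min_prevalence: 0.2
  min_mean_relabund: 0.0
network:
  method: spearman
  rho_min: 0.6
  q_max: 0.05
  clr: false
roles:
  z_threshold: 2.5
  p_threshold: 0.62
sem:
  model: sem_model.txt
  n: null        # defaults to the number of metadata rows
outdir: out
seed: 42
log_level: INFO
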