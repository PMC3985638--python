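# Tutorial system: 8 chains x 100 monomers at the full nucleus' volume
# fraction (R0 = 10 * (800/6098)^(1/3)), 10% active at T_a = 20, with a
# gene-rich (c0) and a gene-poor (c1) chain mirroring the chr19/chr18
# density contrast.  Runs in ~1 minute on one core.
seed: 1
genome:
  karyotype: examples/tutorial_karyotype.csv
  track: synthesize
  constraints: {c0: 62.0, c1: 18.6}
  default_mean: 25.0
  mode: inhomogeneous
  active_fraction: 0.10
  T_a: 20.0
geometry:
  kind: sphere
  R0: 5.0812
schedule:
  n_steps: 50000
  n_burnin: 30000
  sample_every: 5000
ne:
  enabled: false
out: tutorial_out
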