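# full-pipeline configuration for `tmtdiff run --config examples/run.yaml
#   --seed 42 --outdir results/`
synthetic:
  n_proteins: 1000
  n_case: 15
  n_control: 15
  n_batches: 3
  spike_fraction: 0.10
  missing_rate: 0.02
sam:
  s0: 0.1
  n_permutations: 250
bootauc:
  n_bootstrap: 1000
  n_label_permutations: 20
seed: 42
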