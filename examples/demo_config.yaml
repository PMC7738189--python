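# Demo pipeline configuration: small synthetic study, both genotypes,
# feature extraction and a TF-driven joint fit.
# Run with:  hbaccess report --config examples/demo_config.yaml --outdir demo_out
seed: 7
model_class: tf_driven
genotypes: [wild-type, zelda-null]
n_embryos: 3
n_nuclei_per_bin: 6
noise_sd: 2.5          # RNAP units, ~5% of the full trace signal
activity_min_fraction: 0.30
fit:
  enabled: true
  model_class: tf_driven
  fixed: {m: 3}
  n_starts: 3
explore:
  enabled: false
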