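# Group comparison of subthreshold variability in the model neuron:
# calibrates channels, matches depolarization across the four conditions,
# and emits the CV table normalized to control, plus the integrate-and-fire
# compensation curves.
seed: 1
out_dir: runs/group_variability
stages:
  - name: hh_group_cv
    params:
      noise: external
      n_trials: 100
  - name: if_compensation
    params:
      rheobase_fraction: 0.70
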