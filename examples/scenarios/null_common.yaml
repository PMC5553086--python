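label: null-common
haplotype_freqs:
- 0.36
- 0.24
- 0.24
- 0.16000000000000003
penetrance:
  form: logit_linear
  alpha: -2.197224577336219
  beta: 0.0
  gamma: 0.0
  interaction: 0.0
n_cases: 500
n_controls: 500
replicates: 5000
seed: 1
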