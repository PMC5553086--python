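label: lowmaf-ld
haplotype_freqs:
- 0.8456071478515882
- 0.046483325050747405
- 0.046483325050747405
- 0.06142620204691707
penetrance:
  form: logit_linear
  alpha: -2.197224577336219
  beta: 0.25
  gamma: 0.25
  interaction: 0.25
n_cases: 500
n_controls: 500
replicates: 1000
seed: 1
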