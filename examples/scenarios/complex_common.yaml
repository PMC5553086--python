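label: complex-common
haplotype_freqs:
- 0.36
- 0.24
- 0.24
- 0.16000000000000003
penetrance:
  form: table
  log_odds:
  - - -2.197224577336219
    - -2.032224577336219
    - -1.8372245773362192
  - - -2.032224577336219
    - -1.807224577336219
    - -2.0022245773362193
  - - -1.8372245773362192
    - -2.0022245773362193
    - -1.657224577336219
n_cases: 500
n_controls: 500
replicates: 1000
seed: 1
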