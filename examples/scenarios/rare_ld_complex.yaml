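label: rare-ld-complex
haplotype_freqs:
- 0.9856438201963825
- 0.002118914349495054
- 0.002118914349495054
- 0.010118351104627327
penetrance:
  form: table
  log_odds:
  - - -2.197224577336219
    - -1.647224577336219
    - -0.9972245773362192
  - - -1.647224577336219
    - -0.8972245773362191
    - -1.5472245773362192
  - - -0.9972245773362192
    - -1.5472245773362192
    - -0.3972245773362191
n_cases: 500
n_controls: 500
replicates: 1000
seed: 1
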