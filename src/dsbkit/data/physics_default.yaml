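# Default parametric track-model physics for dsbkit.
# stopping_table rows: [electron energy MeV, LET keV/um].
# Values are illustrative electron collision stopping powers in liquid
# water, provided as editable model inputs; they are NOT asserted as
# measured cross-sections and can be replaced freely.
stopping_table:
  - [0.001, 12.6]
  - [0.01, 2.26]
  - [0.1, 0.412]
  - [1.0, 0.185]
  - [6.0, 0.192]
mean_deposit_ev: 40.0
deposit_min_ev: 5.0
deposit_max_ev: 500.0
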