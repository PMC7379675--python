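dose_gy,p_dsb,sem
25,0.043,0.002
50,0.081,0.003
100,0.149,0.006
150,0.196,0.005
200,0.242,0.011
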