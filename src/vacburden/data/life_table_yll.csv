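age,yll
2,90.01
7,85.02
12,80.03
16,76.04
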