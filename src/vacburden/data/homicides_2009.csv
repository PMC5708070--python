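band_low,band_high,deaths
0,4,405
5,9,87
10,14,110
15,17,416
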