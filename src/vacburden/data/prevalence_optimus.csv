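exposure,sex,p
sexual,total,0.072
sexual,male,0.061
sexual,female,0.085
physical,total,0.261
physical,male,0.24
physical,female,0.287
emotional,total,0.126
emotional,male,0.097
emotional,female,0.162
neglect,total,0.122
neglect,male,0.098
neglect,female,0.151
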