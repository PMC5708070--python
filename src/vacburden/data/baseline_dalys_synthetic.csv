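exposure,outcome,sex,dalys
sexual,anxiety,total,140822.5261044177
sexual,drug_abuse,total,130989.4638764325
sexual,stds,total,39508.77777777778
sexual,stds,female,0.0
sexual,self_harm,total,381912.809178744
sexual,alcohol_abuse,male,516953.98907103814
sexual,alcohol_abuse,female,367118.8235294117
sexual,interpersonal_violence,male,621070.524590164
sexual,interpersonal_violence,female,248444.57822277848
sexual,depression,female,241791.3864625302
sexual,hiv,female,3747342.5607843124
physical,smi,total,937218.8110456968
physical,anxiety,total,140814.4768434496
physical,alcohol_abuse,total,950058.6314872866
physical,drug_abuse,total,130990.85840413127
physical,interpersonal_violence,total,1011835.5244785018
physical,interpersonal_violence,male,0.0
physical,interpersonal_violence,female,0.0
physical,self_harm,total,381915.00057640794
physical,hiv,female,3747346.4116886384
emotional,smi,total,937226.673350042
emotional,anxiety,total,140815.72646733111
emotional,alcohol_abuse,total,950059.9727891154
emotional,alcohol_abuse,male,0.0
emotional,drug_abuse,total,130979.10259388312
emotional,interpersonal_violence,total,1011832.0340975894
emotional,self_harm,total,381916.2375073486
emotional,hiv,female,3747342.2204995686
neglect,anxiety,total,140809.85739950594
neglect,depression,male,152917.8708915145
neglect,depression,female,264860.7135059202
neglect,drug_abuse,male,85327.3560090703
neglect,alcohol_abuse,female,205432.46830652785
neglect,stds,female,17261.5792154865
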