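exposure,outcome,daly_loss,economic_value_million_zar
sexual,depression,14127,1032
sexual,anxiety,7941,580
sexual,alcohol_abuse,70520,5152
sexual,drug_abuse,18122,1324
sexual,stds,1106,81
sexual,hiv,181841,13285
sexual,interpersonal_violence,36764,2686
sexual,self_harm,44677,3264
physical,smi,90597,6619
physical,anxiety,18236,1332
physical,alcohol_abuse,119261,8713
physical,drug_abuse,14041,1026
physical,hiv,816045,59621
physical,interpersonal_violence,45403,3317
physical,self_harm,86984,6355
emotional,smi,42824,3129
emotional,anxiety,13767,1006
emotional,alcohol_abuse,40128,2932
emotional,drug_abuse,6434,470
emotional,hiv,458238,33479
emotional,interpersonal_violence,33290,2432
emotional,self_harm,55520,4056
neglect,depression,48008,3507
neglect,anxiety,11515,841
neglect,alcohol_abuse,29717,2171
neglect,drug_abuse,3604,263
neglect,stds,960,70
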