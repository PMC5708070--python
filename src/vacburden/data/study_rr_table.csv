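study_id,exposure,outcome,sex,rr,n,paf_printed
pooled_00,sexual,anxiety,total,1.83,1,0.06
pooled_01,sexual,drug_abuse,total,3.23,1,0.14
pooled_02,sexual,stds,total,1.4,1,0.03
pooled_03,sexual,self_harm,total,2.84,1,0.12
pooled_04,sexual,alcohol_abuse,male,2.2,1,0.07
pooled_05,sexual,interpersonal_violence,male,1.5,1,0.0296
pooled_06,sexual,depression,female,1.73,1,0.06
pooled_07,sexual,alcohol_abuse,female,2.25,1,0.1
pooled_08,sexual,stds,female,2.0,1,0.08
pooled_09,sexual,hiv,female,1.6,1,0.05
pooled_10,sexual,interpersonal_violence,female,1.94,1,0.074
pooled_11,physical,smi,total,1.41,1,0.1
pooled_12,physical,anxiety,total,1.57,1,0.13
pooled_13,physical,alcohol_abuse,total,1.55,1,0.13
pooled_14,physical,drug_abuse,total,1.46,1,0.11
pooled_15,physical,interpersonal_violence,total,1.18,1,0.0449
pooled_16,physical,self_harm,total,2.13,1,0.23
pooled_17,physical,interpersonal_violence,male,1.35,1,0.0775
pooled_18,physical,hiv,female,1.97,1,0.22
pooled_19,physical,interpersonal_violence,female,1.48,1,0.1211
pooled_20,emotional,smi,total,1.38,1,0.05
pooled_21,emotional,anxiety,total,1.86,1,0.1
pooled_22,emotional,alcohol_abuse,total,1.35,1,0.04
pooled_23,emotional,drug_abuse,total,1.41,1,0.05
pooled_24,emotional,interpersonal_violence,total,1.27,1,0.0329
pooled_25,emotional,self_harm,total,2.35,1,0.15
pooled_26,emotional,alcohol_abuse,male,1.33,1,0.03
pooled_27,emotional,hiv,female,1.86,1,0.12
pooled_28,neglect,anxiety,total,1.73,1,0.08
pooled_29,neglect,depression,male,2.9,1,0.16
pooled_30,neglect,drug_abuse,male,1.45,1,0.04
pooled_31,neglect,depression,female,1.66,1,0.09
pooled_32,neglect,alcohol_abuse,female,2.12,1,0.14
pooled_33,neglect,stds,female,1.39,1,0.06
pooled_34,witnessing,anxiety,total,1.59,1,0.13
pooled_35,witnessing,interpersonal_violence,male,1.86,1,0.1591
pooled_36,witnessing,interpersonal_violence,female,1.71,1,0.1648
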