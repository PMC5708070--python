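province,amount_thousand_zar
Eastern Cape,216512
Free State,78284
Western Cape,175376
North West,55023
Gauteng,507563
KZN,324436
Northern Cape,36687
Mpumalanga,54092
Limpopo,133190
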