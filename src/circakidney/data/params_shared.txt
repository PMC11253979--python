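# circakidney calibrated shared parameters
diuretic_efficacy = 0.8495415047315986
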