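adduct	mass_delta	charge
[M+H]+	1.00727646	1
[M+Na]+	22.98922070	1
[M+K]+	38.96315810	1
[M+NH4]+	18.03382555	1
[M-H]-	-1.00727646	-1
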