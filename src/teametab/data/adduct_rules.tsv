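name	polarity	n	z	mass_delta	requires_elements	requires_ion
[M+H]+	positive	1	1	1.007276	-	-
[M+Na]+	positive	1	1	22.989218	-	-
[M+K]+	positive	1	1	38.963158	-	-
[M+NH4]+	positive	1	1	18.033823	-	NH4+
[2M+H]+	positive	2	1	1.007276	-	-
[M+H-H2O]+	positive	1	1	-17.003289	O	-
[M+H-NH3]+	positive	1	1	-16.019273	N	-
[M-H]-	negative	1	1	-1.007276	-	-
[M+Cl]-	negative	1	1	34.969402	-	-
[M+HCOO]-	negative	1	1	44.998201	-	HCOO-
[2M-H]-	negative	2	1	-1.007276	-	-
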