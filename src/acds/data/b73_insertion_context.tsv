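class	genic	repetitive	intergenic
Ds1	37	155	139
Ds2	5	13	21
Ds-l3	2	25	17
Ds-l4	34	180	272
Ac-like	0	2	1
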