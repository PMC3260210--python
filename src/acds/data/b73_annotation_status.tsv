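class	new	partial	full
Ds1	143	4	184
Ds2	11	26	2
Ds-l3	2	42	0
Ds-l4	424	62	0
Ac-like	0	3	0
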