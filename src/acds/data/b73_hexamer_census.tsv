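chromosome	Ds1	Ds2	Ds-l3	Ds-l4	Ac-like
1	3	7	3	76	1
2	0	5	3	42	1
3	0	2	6	48	0
4	4	2	5	63	0
5	5	4	3	42	1
6	0	0	3	30	0
7	2	3	5	37	0
8	1	6	5	38	0
9	1	2	0	24	0
10	0	4	3	32	0
Unknown	1	4	1	6	0
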