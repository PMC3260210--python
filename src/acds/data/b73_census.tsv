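chromosome	Ds1	Ds2	Ds-l3	Ds-l4	Ac-like
1	48	7	4	84	1
2	45	5	3	46	1
3	40	2	6	53	0
4	28	2	5	69	0
5	42	4	4	47	1
6	20	0	3	33	0
7	26	3	5	42	0
8	31	6	8	43	0
9	26	2	0	28	0
10	17	4	3	35	0
Unknown	8	4	3	6	0
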