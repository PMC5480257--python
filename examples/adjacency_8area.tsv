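	A	B	C	D	E	F	G	H
A	0	0	0	0	0	0	0	0
B	0	0	0	0	0	0	0	0
C	0	0	0	0	0	0	0	0
D	0	0	0	0	1	1	0	0
E	0	0	0	1	0	0	1	0
F	0	0	0	1	0	0	0	0
G	0	0	0	0	1	0	0	0
H	0	0	0	0	0	0	0	0
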