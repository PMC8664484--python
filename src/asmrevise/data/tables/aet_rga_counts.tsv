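species	NBS	CNL	TNL	CN	TN	NL	RLP	RLK	TM_CC	total
Ae_tauschii	119	215	0	85	3	221	145	991	142	1921
T_aestivum_D	145	235	0	105	4	280	206	1094	174	2243
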