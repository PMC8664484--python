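complete	unimag	unipoa	ptrep	label
1	A	A	A	LC
1	A	A	I	unclassified
1	A	A	S	REP
1	A	I	A	unclassified
1	A	I	I	unclassified
1	A	I	S	REP
1	A	S	A	HC
1	A	S	I	HC
1	A	S	S	REP
1	I	A	A	unclassified
1	I	A	I	unclassified
1	I	A	S	unclassified
1	I	I	A	unclassified
1	I	I	I	unclassified
1	I	I	S	unclassified
1	I	S	A	unclassified
1	I	S	I	unclassified
1	I	S	S	unclassified
1	S	A	A	HC
1	S	A	I	HC
1	S	A	S	HC
1	S	I	A	HC
1	S	I	I	HC
1	S	I	S	HC
1	S	S	A	HC
1	S	S	I	HC
1	S	S	S	HC
0	A	A	A	unclassified
0	A	A	I	unclassified
0	A	A	S	unclassified
0	A	I	A	unclassified
0	A	I	I	unclassified
0	A	I	S	unclassified
0	A	S	A	LC
0	A	S	I	LC
0	A	S	S	unclassified
0	I	A	A	unclassified
0	I	A	I	unclassified
0	I	A	S	unclassified
0	I	I	A	unclassified
0	I	I	I	unclassified
0	I	I	S	unclassified
0	I	S	A	LC
0	I	S	I	LC
0	I	S	S	unclassified
0	S	A	A	LC
0	S	A	I	LC
0	S	A	S	unclassified
0	S	I	A	LC
0	S	I	I	LC
0	S	I	S	unclassified
0	S	S	A	LC
0	S	S	I	LC
0	S	S	S	unclassified
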