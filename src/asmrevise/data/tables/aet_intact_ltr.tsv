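chrom	copia_v40	copia_v50	gypsy_v40	gypsy_v50	unknown_v40	unknown_v50
Chr1	1674	1941	3139	3530	1637	1795
Chr2	2030	2434	3922	4427	2184	2375
Chr3	1942	2254	3777	4091	2067	2197
Chr4	1625	1905	3461	3879	1736	1884
Chr5	1975	2392	3485	3888	1890	2099
Chr6	1603	1931	3019	3429	1663	1799
Chr7	2081	2439	3689	4080	2134	2307
Total	12930	15296	24492	27324	13311	14456
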