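seq_id	total_length	gap_length	effective_length	gap_number
Chr1	502330251	10377979	491952272	11744
Chr2	651661114	10780418	640880696	14522
Chr3	627182665	11118990	616063675	14404
Chr4	526018785	9454858	516563927	10892
Chr5	577375663	14628972	562746691	13506
Chr6	496019527	9112991	486906536	11357
Chr7	644716137	17324389	627391748	15384
Total	4025304142	82798597	3942505545	91809
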