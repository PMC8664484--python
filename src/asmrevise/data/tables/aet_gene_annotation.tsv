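metric	hc_v40	lc_v40	hc_v50	lc_v50
total_genes	39635	43495	32885	35903
single_exon_genes	15389	36567	9837	25186
multi_exon_genes	24246	6928	23048	10717
mean_cds_length	1133	319	1250	593
median_cds_length	942	258	1071	435
mean_exons_per_transcript	3.9	1.2	4.45	1.68
median_exons_per_transcript	2	1	3	1
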