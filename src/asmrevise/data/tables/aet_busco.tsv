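annotation	total	complete_single	complete_duplicated	fragmented	missing
v40	1440	1268	21	58	93
v50	1440	1350	24	16	50
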