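class	elements	length_bp	genome_pct
LTR/Gypsy	853285	1333833165	33.17
LTR/Copia	383555	644052368	16.02
LTR/Unknown	456559	611381110	15.20
Non-LTR/LINE	192648	80369034	2.00
Non-LTR/SINE	19503	3344990	0.08
CACTA	201749	203285995	5.05
Mutator	29706	10397597	0.26
PIF-Harbinger	77072	22128071	0.55
Tc1-Mariner	166095	48513995	1.2
hAT	17127	3870055	0.09
Helitron	219796	113044338	2.81
MITE/Stowaway	1139	174827	0.00
MITE/Tourist	453	80546	0.00
DNA/unknown	1245	296555	0.01
Unspecified	393632	410074883	10.20
Total interspersed	3013564	3484847529	86.65
Low complexity	20328	1104950	0.03
Simple repeat	173933	7922189	0.20
Total	3207825	3493874668	86.88
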