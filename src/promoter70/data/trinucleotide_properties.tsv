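word	Bendability	NucleosomePositioning
AAA	-0.274	-36
AAC	-0.205	-9
AAG	-0.081	6
AAT	-0.28	-30
ACA	-0.006	8
ACC	-0.032	8
ACG	-0.033	11
ACT	-0.183	11
AGA	0.027	-9
AGC	0.017	25
AGG	-0.057	8
AGT	-0.183	11
ATA	0.182	-13
ATC	-0.11	7
ATG	0.134	18
ATT	-0.28	-30
CAA	0.015	-9
CAC	0.04	17
CAG	0.175	-2
CAT	0.134	18
CCA	-0.246	8
CCC	-0.012	13
CCG	-0.136	2
CCT	-0.057	8
CGA	-0.003	31
CGC	-0.077	25
CGG	-0.136	2
CGT	-0.033	11
CTA	0.09	-18
CTC	0.031	8
CTG	0.175	-2
CTT	-0.081	6
GAA	-0.037	-12
GAC	-0.013	8
GAG	0.031	8
GAT	-0.11	7
GCA	0.076	13
GCC	0.107	45
GCG	-0.077	25
GCT	0.017	25
GGA	0.013	-5
GGC	0.107	45
GGG	-0.012	13
GGT	-0.032	8
GTA	0.025	-6
GTC	-0.013	8
GTG	0.04	17
GTT	-0.205	-9
TAA	0.068	-20
TAC	0.025	-6
TAG	0.09	-18
TAT	0.182	-13
TCA	0.194	8
TCC	0.013	-5
TCG	-0.003	31
TCT	0.027	-9
TGA	0.194	8
TGC	0.076	13
TGG	-0.246	8
TGT	-0.006	8
TTA	0.068	-20
TTC	-0.037	-12
TTG	0.015	-9
TTT	-0.274	-36
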