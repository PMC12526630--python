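# Relative adaptiveness (w) of E. coli codons, Sharp & Li (1987) Table 1;
# the default CAI reference table of CodonW 1.4.2. Stop codons carry no weight.
codon	w
AAA	1
AAC	1
AAG	0.253
AAT	0.051
ACA	0.076
ACC	1
ACG	0.099
ACT	0.965
AGA	0.004
AGC	0.41
AGG	0.002
AGT	0.085
ATA	0.003
ATC	1
ATG	1
ATT	0.185
CAA	0.124
CAC	1
CAG	1
CAT	0.291
CCA	0.135
CCC	0.012
CCG	1
CCT	0.07
CGA	0.004
CGC	0.356
CGG	0.004
CGT	1
CTA	0.007
CTC	0.037
CTG	1
CTT	0.042
GAA	1
GAC	1
GAG	0.259
GAT	0.434
GCA	0.586
GCC	0.122
GCG	0.424
GCT	1
GGA	0.01
GGC	0.724
GGG	0.019
GGT	1
GTA	0.495
GTC	0.066
GTG	0.221
GTT	1
TAA	0
TAC	1
TAG	0
TAT	0.239
TCA	0.077
TCC	0.744
TCG	0.017
TCT	1
TGA	0
TGC	1
TGG	1
TGT	0.5
TTA	0.02
TTC	1
TTG	0.02
TTT	0.296
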