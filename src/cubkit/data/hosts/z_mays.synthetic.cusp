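# SYNTHETIC codon usage table for host 'z_mays' — NOT measured data.
# Constructed stand-in emulating the host's approximate GC3 character
# (target GC3s ~0.55); see data/hosts/MANIFEST.md. cusp-style columns:
#Codon AA Fraction Frequency Number
TTT F 0.438 20.821 20821
TTC F 0.562 26.731 26731
TTA L 0.112 7.651 7651
TTG L 0.156 10.697 10697
CTT L 0.149 10.230 10230
CTC L 0.162 11.082 11082
CTA L 0.131 8.990 8990
CTG L 0.290 19.846 19846
TCT S 0.216 18.084 18084
TCC S 0.178 14.913 14913
TCA S 0.130 10.865 10865
TCG S 0.274 22.962 22962
AGT S 0.105 8.758 8758
AGC S 0.098 8.228 8228
TAT Y 0.262 9.066 9066
TAC Y 0.738 25.471 25471
TGT C 0.412 2.920 2920
TGC C 0.588 4.164 4164
TGG W 1.000 3.114 3114
CCT P 0.213 11.898 11898
CCC P 0.157 8.757 8757
CCA P 0.390 21.832 21832
CCG P 0.241 13.461 13461
CAT H 0.205 4.744 4744
CAC H 0.795 18.437 18437
CAA Q 0.343 13.555 13555
CAG Q 0.657 25.957 25957
CGT R 0.132 8.196 8196
CGC R 0.140 8.743 8743
CGA R 0.119 7.414 7414
CGG R 0.260 16.207 16207
AGA R 0.146 9.090 9090
AGG R 0.202 12.591 12591
ATT I 0.226 7.760 7760
ATC I 0.489 16.798 16798
ATA I 0.285 9.767 9767
ATG M 1.000 23.494 23494
ACT T 0.070 3.997 3997
ACC T 0.422 24.148 24148
ACA T 0.220 12.592 12592
ACG T 0.287 16.428 16428
AAT N 0.349 21.651 21651
AAC N 0.651 40.469 40469
AAA K 0.515 28.059 28059
AAG K 0.485 26.419 26419
GTT V 0.281 23.054 23054
GTC V 0.370 30.369 30369
GTA V 0.171 13.997 13997
GTG V 0.178 14.555 14555
GCT A 0.265 17.850 17850
GCC A 0.302 20.349 20349
GCA A 0.236 15.942 15942
GCG A 0.197 13.319 13319
GAT D 0.646 36.917 36917
GAC D 0.354 20.243 20243
GAA E 0.763 44.507 44507
GAG E 0.237 13.801 13801
GGT G 0.268 20.356 20356
GGC G 0.370 28.109 28109
GGA G 0.086 6.563 6563
GGG G 0.276 21.010 21010
TAA * 0.500 1.000 1000
TAG * 0.250 0.500 500
TGA * 0.250 0.500 500
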