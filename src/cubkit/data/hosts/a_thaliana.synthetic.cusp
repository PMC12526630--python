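# SYNTHETIC codon usage table for host 'a_thaliana' — NOT measured data.
# Constructed stand-in emulating the host's approximate GC3 character
# (target GC3s ~0.42); see data/hosts/MANIFEST.md. cusp-style columns:
#Codon AA Fraction Frequency Number
TTT F 0.512 14.493 14493
TTC F 0.488 13.830 13830
TTA L 0.148 16.376 16376
TTG L 0.172 19.004 19004
CTT L 0.208 23.002 23002
CTC L 0.156 17.222 17222
CTA L 0.211 23.298 23298
CTG L 0.105 11.557 11557
TCT S 0.196 15.350 15350
TCC S 0.185 14.434 14434
TCA S 0.161 12.564 12564
TCG S 0.141 10.990 10990
AGT S 0.156 12.178 12178
AGC S 0.162 12.619 12619
TAT Y 0.573 20.542 20542
TAC Y 0.427 15.290 15290
TGT C 0.479 5.033 5033
TGC C 0.521 5.472 5472
TGG W 1.000 8.778 8778
CCT P 0.278 8.705 8705
CCC P 0.194 6.079 6079
CCA P 0.257 8.030 8030
CCG P 0.271 8.463 8463
CAT H 0.593 10.244 10244
CAC H 0.407 7.032 7032
CAA Q 0.554 22.427 22427
CAG Q 0.446 18.064 18064
CGT R 0.310 18.096 18096
CGC R 0.069 4.003 4003
CGA R 0.182 10.600 10600
CGG R 0.121 7.032 7032
AGA R 0.166 9.699 9699
AGG R 0.152 8.877 8877
ATT I 0.575 24.363 24363
ATC I 0.189 8.011 8011
ATA I 0.235 9.969 9969
ATG M 1.000 22.866 22866
ACT T 0.357 16.599 16599
ACC T 0.198 9.212 9212
ACA T 0.292 13.558 13558
ACG T 0.152 7.071 7071
AAT N 0.554 29.417 29417
AAC N 0.446 23.705 23705
AAA K 0.565 39.218 39218
AAG K 0.435 30.146 30146
GTT V 0.394 18.473 18473
GTC V 0.250 11.743 11743
GTA V 0.226 10.585 10585
GTG V 0.130 6.118 6118
GCT A 0.267 26.114 26114
GCC A 0.130 12.694 12694
GCA A 0.253 24.739 24739
GCG A 0.351 34.357 34357
GAT D 0.502 35.377 35377
GAC D 0.498 35.148 35148
GAA E 0.540 29.668 29668
GAG E 0.460 25.249 25249
GGT G 0.451 33.503 33503
GGC G 0.120 8.940 8940
GGA G 0.246 18.265 18265
GGG G 0.182 13.507 13507
TAA * 0.500 1.000 1000
TAG * 0.250 0.500 500
TGA * 0.250 0.500 500
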