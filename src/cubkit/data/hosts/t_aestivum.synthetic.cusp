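# SYNTHETIC codon usage table for host 't_aestivum' — NOT measured data.
# Constructed stand-in emulating the host's approximate GC3 character
# (target GC3s ~0.60); see data/hosts/MANIFEST.md. cusp-style columns:
#Codon AA Fraction Frequency Number
TTT F 0.374 14.974 14974
TTC F 0.626 25.088 25088
TTA L 0.082 5.749 5749
TTG L 0.164 11.506 11506
CTT L 0.066 4.601 4601
CTC L 0.347 24.382 24382
CTA L 0.103 7.231 7231
CTG L 0.239 16.776 16776
TCT S 0.165 13.147 13147
TCC S 0.115 9.154 9154
TCA S 0.172 13.674 13674
TCG S 0.228 18.147 18147
AGT S 0.062 4.940 4940
AGC S 0.258 20.522 20522
TAT Y 0.381 17.342 17342
TAC Y 0.619 28.160 28160
TGT C 0.641 7.015 7015
TGC C 0.359 3.927 3927
TGG W 1.000 13.095 13095
CCT P 0.178 7.802 7802
CCC P 0.264 11.564 11564
CCA P 0.204 8.937 8937
CCG P 0.354 15.507 15507
CAT H 0.411 10.426 10426
CAC H 0.589 14.935 14935
CAA Q 0.213 10.009 10009
CAG Q 0.787 36.961 36961
CGT R 0.276 15.419 15419
CGC R 0.258 14.431 14431
CGA R 0.067 3.767 3767
CGG R 0.168 9.407 9407
AGA R 0.122 6.842 6842
AGG R 0.108 6.056 6056
ATT I 0.283 17.546 17546
ATC I 0.288 17.852 17852
ATA I 0.430 26.676 26676
ATG M 1.000 34.845 34845
ACT T 0.248 13.238 13238
ACC T 0.298 15.933 15933
ACA T 0.103 5.531 5531
ACG T 0.351 18.783 18783
AAT N 0.376 18.042 18042
AAC N 0.624 29.899 29899
AAA K 0.577 34.552 34552
AAG K 0.423 25.278 25278
GTT V 0.062 4.463 4463
GTC V 0.279 20.060 20060
GTA V 0.256 18.457 18457
GTG V 0.403 28.998 28998
GCT A 0.128 7.550 7550
GCC A 0.390 23.085 23085
GCA A 0.077 4.527 4527
GCG A 0.405 23.966 23966
GAT D 0.639 23.940 23940
GAC D 0.361 13.530 13530
GAA E 0.559 36.286 36286
GAG E 0.441 28.622 28622
GGT G 0.119 8.939 8939
GGC G 0.414 31.018 31018
GGA G 0.112 8.403 8403
GGG G 0.354 26.487 26487
TAA * 0.500 1.000 1000
TAG * 0.250 0.500 500
TGA * 0.250 0.500 500
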