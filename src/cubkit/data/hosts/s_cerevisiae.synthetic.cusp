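# SYNTHETIC codon usage table for host 's_cerevisiae' — NOT measured data.
# Constructed stand-in emulating the host's approximate GC3 character
# (target GC3s ~0.38); see data/hosts/MANIFEST.md. cusp-style columns:
#Codon AA Fraction Frequency Number
TTT F 0.739 27.431 27431
TTC F 0.261 9.687 9687
TTA L 0.303 31.274 31274
TTG L 0.102 10.509 10509
CTT L 0.253 26.132 26132
CTC L 0.147 15.227 15227
CTA L 0.154 15.970 15970
CTG L 0.041 4.270 4270
TCT S 0.161 13.222 13222
TCC S 0.146 11.963 11963
TCA S 0.158 13.009 13009
TCG S 0.138 11.309 11309
AGT S 0.313 25.674 25674
AGC S 0.084 6.918 6918
TAT Y 0.588 19.077 19077
TAC Y 0.412 13.385 13385
TGT C 0.624 8.605 8605
TGC C 0.376 5.186 5186
TGG W 1.000 10.619 10619
CCT P 0.334 19.399 19399
CCC P 0.344 19.976 19976
CCA P 0.212 12.302 12302
CCG P 0.111 6.477 6477
CAT H 0.787 22.681 22681
CAC H 0.213 6.149 6149
CAA Q 0.553 21.958 21958
CAG Q 0.447 17.728 17728
CGT R 0.301 18.400 18400
CGC R 0.183 11.168 11168
CGA R 0.116 7.085 7085
CGG R 0.056 3.438 3438
AGA R 0.213 13.040 13040
AGG R 0.131 8.025 8025
ATT I 0.269 14.644 14644
ATC I 0.222 12.119 12119
ATA I 0.509 27.745 27745
ATG M 1.000 18.298 18298
ACT T 0.400 19.591 19591
ACC T 0.280 13.686 13686
ACA T 0.206 10.095 10095
ACG T 0.114 5.595 5595
AAT N 0.583 36.278 36278
AAC N 0.417 25.942 25942
AAA K 0.649 34.025 34025
AAG K 0.351 18.371 18371
GTT V 0.468 31.657 31657
GTC V 0.274 18.509 18509
GTA V 0.132 8.907 8907
GTG V 0.126 8.553 8553
GCT A 0.355 27.848 27848
GCC A 0.220 17.252 17252
GCA A 0.133 10.414 10414
GCG A 0.293 23.015 23015
GAT D 0.610 28.163 28163
GAC D 0.390 18.023 18023
GAA E 0.577 24.269 24269
GAG E 0.423 17.770 17770
GGT G 0.170 10.210 10210
GGC G 0.330 19.794 19794
GGA G 0.363 21.728 21728
GGG G 0.137 8.207 8207
TAA * 0.500 1.000 1000
TAG * 0.250 0.500 500
TGA * 0.250 0.500 500
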