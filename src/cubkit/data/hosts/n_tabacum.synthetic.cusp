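# SYNTHETIC codon usage table for host 'n_tabacum' — NOT measured data.
# Constructed stand-in emulating the host's approximate GC3 character
# (target GC3s ~0.40); see data/hosts/MANIFEST.md. cusp-style columns:
#Codon AA Fraction Frequency Number
TTT F 0.497 22.341 22341
TTC F 0.503 22.570 22570
TTA L 0.250 29.576 29576
TTG L 0.071 8.413 8413
CTT L 0.207 24.561 24561
CTC L 0.086 10.229 10229
CTA L 0.214 25.313 25313
CTG L 0.172 20.418 20418
TCT S 0.239 19.028 19028
TCC S 0.154 12.252 12252
TCA S 0.125 9.923 9923
TCG S 0.114 9.055 9055
AGT S 0.213 16.955 16955
AGC S 0.155 12.342 12342
TAT Y 0.539 16.038 16038
TAC Y 0.461 13.706 13706
TGT C 0.778 16.384 16384
TGC C 0.222 4.662 4662
TGG W 1.000 6.607 6607
CCT P 0.292 15.930 15930
CCC P 0.276 15.101 15101
CCA P 0.278 15.185 15185
CCG P 0.154 8.412 8412
CAT H 0.687 12.060 12060
CAC H 0.313 5.493 5493
CAA Q 0.612 43.596 43596
CAG Q 0.388 27.694 27694
CGT R 0.177 6.229 6229
CGC R 0.095 3.353 3353
CGA R 0.174 6.107 6107
CGG R 0.132 4.631 4631
AGA R 0.324 11.395 11395
AGG R 0.098 3.431 3431
ATT I 0.456 14.950 14950
ATC I 0.244 8.000 8000
ATA I 0.300 9.853 9853
ATG M 1.000 25.250 25250
ACT T 0.326 14.034 14034
ACC T 0.228 9.812 9812
ACA T 0.222 9.564 9564
ACG T 0.225 9.697 9697
AAT N 0.492 18.920 18920
AAC N 0.508 19.497 19497
AAA K 0.756 40.858 40858
AAG K 0.244 13.164 13164
GTT V 0.253 13.039 13039
GTC V 0.254 13.112 13112
GTA V 0.313 16.141 16141
GTG V 0.181 9.348 9348
GCT A 0.276 23.957 23957
GCC A 0.274 23.758 23758
GCA A 0.292 25.343 25343
GCG A 0.158 13.666 13666
GAT D 0.534 27.911 27911
GAC D 0.466 24.326 24326
GAA E 0.476 31.655 31655
GAG E 0.524 34.893 34893
GGT G 0.286 19.508 19508
GGC G 0.191 13.031 13031
GGA G 0.342 23.332 23332
GGG G 0.182 12.391 12391
TAA * 0.500 1.000 1000
TAG * 0.250 0.500 500
TGA * 0.250 0.500 500
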