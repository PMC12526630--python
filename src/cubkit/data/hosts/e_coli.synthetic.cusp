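# SYNTHETIC codon usage table for host 'e_coli' — NOT measured data.
# Constructed stand-in emulating the host's approximate GC3 character
# (target GC3s ~0.55); see data/hosts/MANIFEST.md. cusp-style columns:
#Codon AA Fraction Frequency Number
TTT F 0.409 14.230 14230
TTC F 0.591 20.600 20600
TTA L 0.292 23.031 23031
TTG L 0.120 9.497 9497
CTT L 0.111 8.746 8746
CTC L 0.154 12.140 12140
CTA L 0.061 4.849 4849
CTG L 0.262 20.636 20636
TCT S 0.131 10.712 10712
TCC S 0.100 8.164 8164
TCA S 0.210 17.170 17170
TCG S 0.235 19.261 19261
AGT S 0.138 11.315 11315
AGC S 0.187 15.287 15287
TAT Y 0.697 24.577 24577
TAC Y 0.303 10.683 10683
TGT C 0.397 7.600 7600
TGC C 0.603 11.553 11553
TGG W 1.000 15.450 15450
CCT P 0.069 2.337 2337
CCC P 0.340 11.437 11437
CCA P 0.160 5.383 5383
CCG P 0.431 14.525 14525
CAT H 0.342 9.507 9507
CAC H 0.658 18.330 18330
CAA Q 0.561 31.972 31972
CAG Q 0.439 25.012 25012
CGT R 0.150 10.001 10001
CGC R 0.156 10.389 10389
CGA R 0.142 9.434 9434
CGG R 0.124 8.260 8260
AGA R 0.197 13.078 13078
AGG R 0.231 15.354 15354
ATT I 0.179 9.400 9400
ATC I 0.427 22.447 22447
ATA I 0.394 20.727 20727
ATG M 1.000 10.758 10758
ACT T 0.387 17.839 17839
ACC T 0.093 4.288 4288
ACA T 0.235 10.826 10826
ACG T 0.285 13.158 13158
AAT N 0.519 20.409 20409
AAC N 0.481 18.896 18896
AAA K 0.723 44.995 44995
AAG K 0.277 17.221 17221
GTT V 0.220 13.813 13813
GTC V 0.504 31.653 31653
GTA V 0.067 4.195 4195
GTG V 0.209 13.097 13097
GCT A 0.053 4.125 4125
GCC A 0.190 14.824 14824
GCA A 0.250 19.491 19491
GCG A 0.506 39.449 39449
GAT D 0.252 14.916 14916
GAC D 0.748 44.219 44219
GAA E 0.288 20.501 20501
GAG E 0.712 50.764 50764
GGT G 0.254 16.612 16612
GGC G 0.204 13.371 13371
GGA G 0.237 15.516 15516
GGG G 0.305 19.972 19972
TAA * 0.500 1.000 1000
TAG * 0.250 0.500 500
TGA * 0.250 0.500 500
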