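# glycan 11: sLeX 6-arm, plain core-1 arm
# Neu5Ac(a2,3)Gal(b1,4)[Fuc(a1,3)]GlcNAc(b1,6)[Gal(b1,3)]GalNAc
RES
1b:x-dgal-HEX-1:5
2s:n-acetyl
3b:b-dgal-HEX-1:5
4b:b-dglc-HEX-1:5
5s:n-acetyl
6b:a-lgal-HEX-1:5|6:d
7b:b-dgal-HEX-1:5
8b:a-dgro-dgal-NON-2:6|1:a|2:keto|3:d
9s:n-acetyl
LIN
1:1d(2+1)2n
2:1o(3+1)3d
3:4d(2+1)5n
4:4o(3+1)6d
5:8d(5+1)9n
6:7o(3+2)8d
7:4o(4+1)7d
8:1o(6+1)4d
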