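# glycan 9: extended 6-arm with sLeX, disialylated
# Neu5Ac(a2,3)Gal(b1,4)[Fuc(a1,3)]GlcNAc(b1,3)Gal(b1,4)GlcNAc(b1,6)[Neu5Ac(a2,3)Gal(b1,3)]GalNAc
RES
1b:x-dgal-HEX-1:5
2s:n-acetyl
3b:b-dgal-HEX-1:5
4b:a-dgro-dgal-NON-2:6|1:a|2:keto|3:d
5s:n-acetyl
6b:b-dglc-HEX-1:5
7s:n-acetyl
8b:b-dgal-HEX-1:5
9b:b-dglc-HEX-1:5
10s:n-acetyl
11b:a-lgal-HEX-1:5|6:d
12b:b-dgal-HEX-1:5
13b:a-dgro-dgal-NON-2:6|1:a|2:keto|3:d
14s:n-acetyl
LIN
1:1d(2+1)2n
2:4d(5+1)5n
3:3o(3+2)4d
4:1o(3+1)3d
5:6d(2+1)7n
6:9d(2+1)10n
7:9o(3+1)11d
8:13d(5+1)14n
9:12o(3+2)13d
10:9o(4+1)12d
11:8o(3+1)9d
12:6o(4+1)8d
13:1o(6+1)6d
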