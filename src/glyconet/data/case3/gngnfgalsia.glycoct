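# GnGnFGalSia (synthetic fixture)
# Fuc(a1,6)[GlcNAc(b1,2)Man(a1,6)[Neu5Ac(a2,3)Gal(b1,4)GlcNAc(b1,2)Man(a1,3)]Man(b1,4)GlcNAc(b1,4)]GlcNAc
RES
1b:x-dglc-HEX-1:5
2s:n-acetyl
3b:b-dglc-HEX-1:5
4s:n-acetyl
5b:b-dman-HEX-1:5
6b:a-dman-HEX-1:5
7b:b-dglc-HEX-1:5
8s:n-acetyl
9b:b-dgal-HEX-1:5
10b:a-dgro-dgal-NON-2:6|1:a|2:keto|3:d
11s:n-acetyl
12b:a-dman-HEX-1:5
13b:b-dglc-HEX-1:5
14s:n-acetyl
15b:a-lgal-HEX-1:5|6:d
LIN
1:1d(2+1)2n
2:3d(2+1)4n
3:7d(2+1)8n
4:10d(5+1)11n
5:9o(3+2)10d
6:7o(4+1)9d
7:6o(2+1)7d
8:5o(3+1)6d
9:13d(2+1)14n
10:12o(2+1)13d
11:5o(6+1)12d
12:3o(4+1)5d
13:1o(4+1)3d
14:1o(6+1)15d
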