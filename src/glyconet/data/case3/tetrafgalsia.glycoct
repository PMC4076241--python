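# TetraFGalSia (synthetic fixture)
# Fuc(a1,6)[GlcNAc(b1,6)[GlcNAc(b1,2)]Man(a1,6)[GlcNAc(b1,4)[Neu5Ac(a2,3)Gal(b1,4)GlcNAc(b1,2)]Man(a1,3)]Man(b1,4)GlcNAc(b1,4)]GlcNAc
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
12b:b-dglc-HEX-1:5
13s:n-acetyl
14b:a-dman-HEX-1:5
15b:b-dglc-HEX-1:5
16s:n-acetyl
17b:b-dglc-HEX-1:5
18s:n-acetyl
19b:a-lgal-HEX-1:5|6:d
LIN
1:1d(2+1)2n
2:3d(2+1)4n
3:7d(2+1)8n
4:10d(5+1)11n
5:9o(3+2)10d
6:7o(4+1)9d
7:6o(2+1)7d
8:12d(2+1)13n
9:6o(4+1)12d
10:5o(3+1)6d
11:15d(2+1)16n
12:14o(2+1)15d
13:17d(2+1)18n
14:14o(6+1)17d
15:5o(6+1)14d
16:3o(4+1)5d
17:1o(4+1)3d
18:1o(6+1)19d
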