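# GnGnFGal (synthetic fixture)
# Fuc(a1,6)[GlcNAc(b1,2)Man(a1,6)[Gal(b1,4)GlcNAc(b1,2)Man(a1,3)]Man(b1,4)GlcNAc(b1,4)]GlcNAc
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
10b:a-dman-HEX-1:5
11b:b-dglc-HEX-1:5
12s:n-acetyl
13b:a-lgal-HEX-1:5|6:d
LIN
1:1d(2+1)2n
2:3d(2+1)4n
3:7d(2+1)8n
4:7o(4+1)9d
5:6o(2+1)7d
6:5o(3+1)6d
7:11d(2+1)12n
8:10o(2+1)11d
9:5o(6+1)10d
10:3o(4+1)5d
11:1o(4+1)3d
12:1o(6+1)13d
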