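# TetraF (synthetic fixture)
# Fuc(a1,6)[GlcNAc(b1,6)[GlcNAc(b1,2)]Man(a1,6)[GlcNAc(b1,4)[GlcNAc(b1,2)]Man(a1,3)]Man(b1,4)GlcNAc(b1,4)]GlcNAc
RES
1b:x-dglc-HEX-1:5
2s:n-acetyl
3b:b-dglc-HEX-1:5
4s:n-acetyl
5b:b-dman-HEX-1:5
6b:a-dman-HEX-1:5
7b:b-dglc-HEX-1:5
8s:n-acetyl
9b:b-dglc-HEX-1:5
10s:n-acetyl
11b:a-dman-HEX-1:5
12b:b-dglc-HEX-1:5
13s:n-acetyl
14b:b-dglc-HEX-1:5
15s:n-acetyl
16b:a-lgal-HEX-1:5|6:d
LIN
1:1d(2+1)2n
2:3d(2+1)4n
3:7d(2+1)8n
4:6o(2+1)7d
5:9d(2+1)10n
6:6o(4+1)9d
7:5o(3+1)6d
8:12d(2+1)13n
9:11o(2+1)12d
10:14d(2+1)15n
11:11o(6+1)14d
12:5o(6+1)11d
13:3o(4+1)5d
14:1o(4+1)3d
15:1o(6+1)16d
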