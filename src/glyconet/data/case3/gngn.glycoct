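# GnGn (synthetic fixture)
# GlcNAc(b1,2)Man(a1,6)[GlcNAc(b1,2)Man(a1,3)]Man(b1,4)GlcNAc(b1,4)GlcNAc
RES
1b:x-dglc-HEX-1:5
2s:n-acetyl
3b:b-dglc-HEX-1:5
4s:n-acetyl
5b:b-dman-HEX-1:5
6b:a-dman-HEX-1:5
7b:b-dglc-HEX-1:5
8s:n-acetyl
9b:a-dman-HEX-1:5
10b:b-dglc-HEX-1:5
11s:n-acetyl
LIN
1:1d(2+1)2n
2:3d(2+1)4n
3:7d(2+1)8n
4:6o(2+1)7d
5:5o(3+1)6d
6:10d(2+1)11n
7:9o(2+1)10d
8:5o(6+1)9d
9:3o(4+1)5d
10:1o(4+1)3d
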