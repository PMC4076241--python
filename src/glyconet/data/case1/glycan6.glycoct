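# glycan 6: core-2 with extended (di-LacNAc) 6-arm
# Gal(b1,4)GlcNAc(b1,3)Gal(b1,4)GlcNAc(b1,6)[Gal(b1,3)]GalNAc
RES
1b:x-dgal-HEX-1:5
2s:n-acetyl
3b:b-dgal-HEX-1:5
4b:b-dglc-HEX-1:5
5s:n-acetyl
6b:b-dgal-HEX-1:5
7b:b-dglc-HEX-1:5
8s:n-acetyl
9b:b-dgal-HEX-1:5
LIN
1:1d(2+1)2n
2:1o(3+1)3d
3:4d(2+1)5n
4:7d(2+1)8n
5:7o(4+1)9d
6:6o(3+1)7d
7:4o(4+1)6d
8:1o(6+1)4d
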