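# Case study 2: N-linked antennary processing from GlcNAcMan5GlcNAc2.
name: case2
enzymes: [GnTII, GnTIII, GnTIV, GnTV, ManII, GalT]
glycans:
  - {label: M5Gn, file: m5gn.glycoct}
expected:
  five_enzymes: {species: 14, reactions: 14}
  six_enzymes: {species: 28, reactions: 28}
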