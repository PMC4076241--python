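# Case study 1: O-linked core-2 glycans on PSGL-1.
# The twelve observed glycans plus the core-2 trisaccharide starting
# glycan.  Structures are transcribed from reported cartoons; where a
# cartoon is ambiguous the transcription is resolved toward the
# network the five enzyme activities reproduce (20 species, 28
# reactions, 7 in-silico intermediates).
name: case1
enzymes: [GalT-IV, B3GnT, ST3Gal-I/II, ST3Gal-IV, FT-VII]
glycans:
  - {label: '0', file: glycan0.glycoct}
  - {label: '1', file: glycan1.glycoct}
  - {label: '2', file: glycan2.glycoct}
  - {label: '3', file: glycan3.glycoct}
  - {label: '4', file: glycan4.glycoct}
  - {label: '5', file: glycan5.glycoct}
  - {label: '6', file: glycan6.glycoct}
  - {label: '7', file: glycan7.glycoct}
  - {label: '8', file: glycan8.glycoct}
  - {label: '9', file: glycan9.glycoct}
  - {label: '10', file: glycan10.glycoct}
  - {label: '11', file: glycan11.glycoct}
  - {label: '12', file: glycan12.glycoct}
expected:
  species: 20
  reactions: 28
  intermediates: 7
  start: '0'
  ends: ['5', '9']
  sweep_argmax: 6
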