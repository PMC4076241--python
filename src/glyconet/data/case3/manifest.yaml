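# Case study 3: SYNTHETIC stand-in roster for an MS-annotated N-glycan
# set (the original roster derives from external MALDI-TOF annotation
# of CHO-cell spectra and is not reproducible from printed material).
# Structures lie along the nine-enzyme biosynthetic routes; expected
# metrics are smoke-level only, not binding.
name: case3
enzymes: [GnTI, GnTII, GnTIII, GnTIV, GnTV, ManII, FucT, SiaT, GalT]
glycans:
  - {label: M5, file: m5.glycoct}
  - {label: M5Gn, file: m5gn.glycoct}
  - {label: M4Gn, file: m4gn.glycoct}
  - {label: M3Gn, file: m3gn.glycoct}
  - {label: GnGn, file: gngn.glycoct}
  - {label: GnGnF, file: gngnf.glycoct}
  - {label: GnGnB, file: gngnb.glycoct}
  - {label: GnGnGal, file: gngngal.glycoct}
  - {label: GnGnFGal, file: gngnfgal.glycoct}
  - {label: GnGnFGalSia, file: gngnfgalsia.glycoct}
  - {label: Tri24, file: tri24.glycoct}
  - {label: Tri24B, file: tri24b.glycoct}
  - {label: Tri26, file: tri26.glycoct}
  - {label: Tetra, file: tetra.glycoct}
  - {label: TetraF, file: tetraf.glycoct}
  - {label: TetraFGal, file: tetrafgal.glycoct}
  - {label: TetraFGalSia, file: tetrafgalsia.glycoct}
expected:
  path_source: M3Gn
  path_target: TetraFGalSia
  mz_window: [1400.0, 3300.0]
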