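"""Bundled case-study fixtures.

Three worked systems ship with the package as GlycoCT files plus a YAML
manifest each:

* **case1** — O-linked core-2 elaboration on PSGL-1: the core-2
  trisaccharide "starting glycan" (glycan 0) plus twelve observed
  O-glycans, elaborated by five enzyme activities (GalT-IV, B3GnT,
  ST3Gal-I/II, ST3Gal-IV, FT-VII).  Connection inference over all pairs
  yields a 20-species / 28-reaction master pathway with 7 in-silico
  intermediates; glycans 5 and 9 carry the sialyl-Lewis-X epitope.
* **case2** — N-linked antennary processing from GlcNAcMan5GlcNAc2 with
  GnT II–V + ManII (14 species / 14 reactions at the fixed point) and with
  GalT added (28 / 28).
* **case3** — a synthetic stand-in for an MS-annotated N-glycan roster
  (the original derives from external MALDI-TOF annotation and is not
  reproducible from printed material): structures along the
  nine-enzyme biosynthetic routes, exercised at smoke level only.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import yaml

from .glycan import Glycan
from .glycoct import parse_glycoct

__all__ = ["CaseStudy", "case1_inputs", "case2_inputs", "case3_inputs"]


@dataclasses.dataclass(frozen=True)
class CaseStudy:
    name: str
    glycans: tuple[Glycan, ...]
    glycan_labels: tuple[str, ...]
    enzyme_names: tuple[str, ...]
    expected: dict

    def glycan(self, label: str) -> Glycan:
        return self.glycans[self.glycan_labels.index(label)]


def _load(case: str) -> CaseStudy:
    base = resources.files("glyconet.data") / case
    manifest = yaml.safe_load((base / "manifest.yaml").read_text())
    glycans = []
    labels = []
    for entry in manifest["glycans"]:
        labels.append(str(entry["label"]))
        glycans.append(parse_glycoct((base / entry["file"]).read_text()))
    return CaseStudy(
        name=manifest["name"],
        glycans=tuple(glycans),
        glycan_labels=tuple(labels),
        enzyme_names=tuple(manifest["enzymes"]),
        expected=manifest.get("expected", {}),
    )


def case1_inputs() -> CaseStudy:
    """O-linked PSGL-1 case: 13 glycans, 5 enzyme activities."""
    return _load("case1")


def case2_inputs() -> CaseStudy:
    """N-linked forward-inference case: one seed, 5+1 enzymes."""
    return _load("case2")


def case3_inputs() -> CaseStudy:
    """Synthetic MS-derived N-glycan case: structures + 9 enzymes."""
    return _load("case3")
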